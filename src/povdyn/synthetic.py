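"""Synthetic longitudinal panel generator with known logit-scale ground truth.

Real income-and-mortality panels (youth cohorts followed annually, then
biennially; a 50+ retirement panel) are restricted-access, so every stage of
the pipeline is exercised against panels generated here.  The generator
reproduces the *statistical structure* the estimator assumes:

* three age segments with different nominal interview spacings
  (:data:`povdyn.rates.DEFAULT_SEGMENTS`);
* per-interval survival and state-transition fates drawn from logistic models
  in age and current state -- the same functional form the estimator fits, so
  the estimator's target (:func:`true_rateset`) is known exactly;
* interview intervals drawn from a truncated normal in months, survey weights,
  and wave non-response (optionally state-dependent).

It does not emulate real income distributions, oversampled subgroups, or
design-based weighting; only the binary below/above-threshold state process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .rates import DEFAULT_SEGMENTS, RateSet, Segment, owning_segment

__all__ = [
    "COEF_TERMS",
    "SegmentCoefficients",
    "GroundTruth",
    "WavePlan",
    "PanelDesign",
    "generate_panel",
    "true_rateset",
    "default_truth",
    "default_design",
    "recovery_design",
    "write_panel",
    "read_panel",
    "PANEL_COLUMNS",
]

#: Fixed term order for coefficient vectors.  ``above`` is the indicator of
#: state 2 (above threshold).  Shorter vectors are zero-padded on the right.
COEF_TERMS = ("const", "age", "above", "age:above", "age2")

#: logit magnitude used to encode degenerate probabilities (expit(500) == 1.0
#: in float64) while keeping coefficient arithmetic finite.
_BIG_LOGIT = 500.0

PANEL_COLUMNS = ("person_id", "wave", "age", "state", "alive",
                 "weight", "interval_months", "responded")


def _pad(coefs) -> np.ndarray:
    c = np.asarray(coefs, dtype=float).ravel()
    if c.size > len(COEF_TERMS):
        raise ValueError(f"at most {len(COEF_TERMS)} coefficients {COEF_TERMS}")
    return np.concatenate([c, np.zeros(len(COEF_TERMS) - c.size)])


def _linear_predictor(coefs: np.ndarray, age, above) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    above = np.asarray(above, dtype=float)
    c = _pad(coefs)
    return (c[0] + c[1] * age + c[2] * above + c[3] * age * above
            + c[4] * age ** 2)


def _safe_logit(p: float) -> float:
    if p <= 0.0:
        return -_BIG_LOGIT
    if p >= 1.0:
        return _BIG_LOGIT
    return float(logit(p))


@dataclass(frozen=True)
class SegmentCoefficients:
    """Per-interval logit-scale coefficients for one segment.

    ``survival``  models P(alive at next wave | age, state at current wave);
    ``transition`` models P(above threshold at next wave | survival, age,
    state).  Both are on the segment's nominal interview-interval scale, i.e.
    they describe fates over one wave spacing, not over 12 months.
    """

    survival: np.ndarray
    transition: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "survival", _pad(self.survival))
        object.__setattr__(self, "transition", _pad(self.transition))

    def p_survive(self, age, state) -> np.ndarray:
        return expit(_linear_predictor(self.survival, age,
                                       np.asarray(state) == 2))

    def p_above_next(self, age, state) -> np.ndarray:
        return expit(_linear_predictor(self.transition, age,
                                       np.asarray(state) == 2))

    def to_dict(self) -> dict:
        return {"survival": self.survival.tolist(),
                "transition": self.transition.tolist()}


def _anchored_coefficients(age_lo: int, age_hi: int,
                           p_below: tuple[float, float],
                           p_above: tuple[float, float]) -> np.ndarray:
    """Coefficients (const, age, above, age:above) of the logit-linear model
    passing through the given probabilities at the two anchor ages."""
    lb, hb = (_safe_logit(p) for p in p_below)
    la, ha = (_safe_logit(p) for p in p_above)
    span = float(age_hi - age_lo)
    slope_b = (hb - lb) / span
    slope_a = (ha - la) / span
    const_b = lb - slope_b * age_lo
    const_a = la - slope_a * age_lo
    return np.array([const_b, slope_b, const_a - const_b, slope_a - slope_b])


@dataclass
class GroundTruth:
    """Known data-generating process: one coefficient set per segment.

    Coefficients live on each segment's per-interval scale (the scale the
    pooled regression estimates before annualization), so the generator can
    sample wave-to-wave fates from them directly.
    """

    coefficients: Mapping[str, SegmentCoefficients]
    segments: tuple[Segment, ...] = DEFAULT_SEGMENTS
    label: str = ""

    def __post_init__(self):
        missing = [s.name for s in self.segments
                   if s.name not in self.coefficients]
        if missing:
            raise ValueError(f"no coefficients for segments {missing}")

    def segment_for(self, age) -> Segment:
        """Owning segment, clamped to the edge segments outside the covered
        range (the edge segment's logit line extrapolates)."""
        age = int(age)
        if age < self.segments[0].age_lo:
            return self.segments[0]
        if age > self.segments[-1].age_hi:
            return self.segments[-1]
        return owning_segment(age, self.segments)

    def _coefs_by_age(self, ages: np.ndarray) -> list[SegmentCoefficients]:
        return [self.coefficients[self.segment_for(a).name] for a in ages]

    def p_survive(self, age, state) -> np.ndarray:
        """Per-interval survival probability at integer age(s) and state(s)."""
        age = np.atleast_1d(np.asarray(age))
        state = np.broadcast_to(np.atleast_1d(np.asarray(state)), age.shape)
        out = np.empty(age.shape, dtype=float)
        for i, (a, s) in enumerate(zip(age, state)):
            out[i] = self.coefficients[self.segment_for(a).name].p_survive(a, s)
        return out

    def p_above_next(self, age, state) -> np.ndarray:
        age = np.atleast_1d(np.asarray(age))
        state = np.broadcast_to(np.atleast_1d(np.asarray(state)), age.shape)
        out = np.empty(age.shape, dtype=float)
        for i, (a, s) in enumerate(zip(age, state)):
            out[i] = self.coefficients[self.segment_for(a).name].p_above_next(a, s)
        return out

    def stationary_below(self, age) -> np.ndarray:
        """Stationary below-threshold share of the per-interval conditional
        transition matrix at ``age`` (used for realistic initial states)."""
        age = np.atleast_1d(np.asarray(age))
        t21 = self.p_above_next(age, np.ones_like(age))       # exit below
        t12 = 1.0 - self.p_above_next(age, 2 * np.ones_like(age))  # enter below
        denom = t12 + t21
        out = np.where(denom > 0, t12 / np.where(denom > 0, denom, 1.0), 0.5)
        return out

    def validate(self, ages: Sequence[int] | None = None) -> None:
        """Check the demographic sanity invariants: all implied probabilities
        strictly inside (0, 1) and survival above 0.5 through age 80."""
        if ages is None:
            ages = range(self.segments[0].age_lo, self.segments[-1].age_hi + 1)
        ages = np.asarray(list(ages))
        for state in (1, 2):
            ps = self.p_survive(ages, state)
            pt = self.p_above_next(ages, state)
            for name, p in (("survival", ps), ("transition", pt)):
                bad = ages[(p <= 0.0) | (p >= 1.0) | ~np.isfinite(p)]
                if bad.size:
                    raise ValueError(
                        f"{name} probability outside (0,1) at ages "
                        f"{bad.tolist()} in state {state}")
            low = ages[(ages <= 80) & (ps <= 0.5)]
            if low.size:
                raise ValueError(
                    f"survival <= 0.5 before age 80 at ages {low.tolist()} "
                    f"in state {state}")

    @classmethod
    def from_probabilities(cls, s1, s2, t21, t22,
                           segments: tuple[Segment, ...] = DEFAULT_SEGMENTS,
                           label="") -> "GroundTruth":
        """Age-constant truth from four per-interval probabilities (handy for
        tests; degenerate 0/1 values are encoded with large finite logits)."""
        surv = np.array([_safe_logit(s1), 0.0,
                         _safe_logit(s2) - _safe_logit(s1), 0.0])
        trans = np.array([_safe_logit(t21), 0.0,
                          _safe_logit(t22) - _safe_logit(t21), 0.0])
        coefs = {seg.name: SegmentCoefficients(surv, trans) for seg in segments}
        return cls(coefs, segments, label)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "segments": [
                {"name": s.name, "age_lo": s.age_lo, "age_hi": s.age_hi,
                 "interval_months": s.interval_months}
                for s in self.segments],
            "coefficients": {k: v.to_dict()
                             for k, v in self.coefficients.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        segments = tuple(Segment(s["name"], int(s["age_lo"]), int(s["age_hi"]),
                                 float(s["interval_months"]))
                         for s in d["segments"])
        coefs = {k: SegmentCoefficients(np.asarray(v["survival"]),
                                        np.asarray(v["transition"]))
                 for k, v in d["coefficients"].items()}
        return cls(coefs, segments, d.get("label", ""))


@dataclass(frozen=True)
class WavePlan:
    """Generation plan for one segment: cohort size, number of interview
    waves, and the SD (months) of the interval-length noise.

    ``staggered=False`` emulates a birth-cohort panel: baseline ages are
    capped so the whole follow-up stays inside the segment.  ``staggered=True``
    emulates continuous-entry panels (new cohorts keep joining): baseline ages
    cover the full segment range and follow-up may run past ``age_hi``
    (observations beyond the segment range are simply not used by the
    segment's fit, as when survey data are subset to an age window).
    """

    segment: Segment
    n_persons: int
    waves: int
    interval_sd: float = 1.5
    staggered: bool = False

    def __post_init__(self):
        if self.n_persons < 1 or self.waves < 1:
            raise ValueError("n_persons and waves must be >= 1")
        if self.interval_sd < 0:
            raise ValueError("interval_sd must be >= 0")

    @property
    def span_years(self) -> int:
        return int(round((self.waves - 1) * self.segment.interval_months / 12.0))

    def baseline_range(self) -> tuple[int, int]:
        lo = self.segment.age_lo
        if self.staggered:
            return lo, self.segment.age_hi
        hi = max(lo, self.segment.age_hi - self.span_years)
        return lo, hi


@dataclass
class PanelDesign:
    """Full panel design: per-segment wave plans plus response and weight
    parameters shared across segments."""

    plans: tuple[WavePlan, ...]
    nonresponse: float = 0.05
    below_nonresponse_odds: float = 1.0
    weight_sigma: float = 0.5
    initial_below: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.nonresponse < 1.0):
            raise ValueError("nonresponse probability must lie in [0, 1)")
        if self.below_nonresponse_odds <= 0:
            raise ValueError("below_nonresponse_odds must be positive")
        if self.initial_below is not None and not (0 <= self.initial_below <= 1):
            raise ValueError("initial_below must lie in [0, 1]")
        segs = sorted((p.segment for p in self.plans), key=lambda s: s.age_lo)
        for a, b in zip(segs, segs[1:]):
            if b.age_lo != a.age_hi + 1:
                raise ValueError(
                    f"segments {a.name} and {b.name} do not partition the age "
                    f"range (gap/overlap at ages {a.age_hi}..{b.age_lo})")

    @property
    def segments(self) -> tuple[Segment, ...]:
        return tuple(p.segment for p in self.plans)

    def to_dict(self) -> dict:
        return {
            "plans": [
                {"segment": {"name": p.segment.name,
                             "age_lo": p.segment.age_lo,
                             "age_hi": p.segment.age_hi,
                             "interval_months": p.segment.interval_months},
                 "n_persons": p.n_persons, "waves": p.waves,
                 "interval_sd": p.interval_sd, "staggered": p.staggered}
                for p in self.plans],
            "nonresponse": self.nonresponse,
            "below_nonresponse_odds": self.below_nonresponse_odds,
            "weight_sigma": self.weight_sigma,
            "initial_below": self.initial_below,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelDesign":
        plans = tuple(
            WavePlan(Segment(p["segment"]["name"], int(p["segment"]["age_lo"]),
                             int(p["segment"]["age_hi"]),
                             float(p["segment"]["interval_months"])),
                     int(p["n_persons"]), int(p["waves"]),
                     float(p.get("interval_sd", 1.5)),
                     bool(p.get("staggered", False)))
            for p in d["plans"])
        return cls(plans,
                   nonresponse=float(d.get("nonresponse", 0.05)),
                   below_nonresponse_odds=float(
                       d.get("below_nonresponse_odds", 1.0)),
                   weight_sigma=float(d.get("weight_sigma", 0.5)),
                   initial_below=(None if d.get("initial_below") is None
                                  else float(d["initial_below"])))


def _check_probs(p: np.ndarray, ages: np.ndarray, states: np.ndarray,
                 what: str) -> None:
    bad = ~np.isfinite(p) | (p < 0.0) | (p > 1.0)
    if np.any(bad):
        pairs = sorted({(int(a), int(s))
                        for a, s in zip(ages[bad], states[bad])})
        raise ValueError(f"{what} probability undefined at (age, state) "
                         f"pairs {pairs}")


def generate_panel(truth: GroundTruth, design: PanelDesign,
                   seed: int) -> pd.DataFrame:
    """Sample a longitudinal panel from ``truth`` under ``design``.

    Within each segment, persons enter at a baseline age drawn uniformly so
    that their last scheduled wave still falls inside the segment, then are
    interviewed ``waves`` times.  Between waves, survival and (conditional on
    survival) the next income state are drawn from the truth's per-interval
    logistic models at the person's current integer age and state.  Death is
    always ascertained (an ``alive=0`` row at the next wave); non-response
    only hides the income state.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    next_id = 0
    base_nr_logit = _safe_logit(design.nonresponse)
    nr_odds_shift = float(np.log(design.below_nonresponse_odds))

    for plan in design.plans:
        seg = plan.segment
        n = plan.n_persons
        pid = np.arange(next_id, next_id + n)
        next_id += n

        lo, hi = plan.baseline_range()
        baseline = rng.integers(lo, hi + 1, size=n)
        weight = rng.lognormal(mean=0.0, sigma=design.weight_sigma, size=n)
        weight /= weight.mean()

        if design.initial_below is None:
            p0 = truth.stationary_below(baseline)
        else:
            p0 = np.full(n, design.initial_below)
        state = np.where(rng.random(n) < p0, 1, 2).astype(float)

        age = baseline.astype(int).copy()
        cum_months = np.zeros(n)
        alive = np.ones(n, dtype=bool)
        dead_recorded = np.zeros(n, dtype=bool)

        for w in range(plan.waves):
            active = ~dead_recorded
            # response: baseline wave always responds; afterwards a per-wave
            # Bernoulli, with odds shifted for persons currently below
            if w == 0 or design.nonresponse == 0.0:
                responded = np.ones(n, dtype=bool)
            else:
                p_nr = expit(base_nr_logit
                             + nr_odds_shift * (state == 1).astype(float))
                responded = rng.random(n) >= p_nr
            responded = responded & alive

            # interval to the next wave, truncated normal in months
            if w < plan.waves - 1:
                months = rng.normal(seg.interval_months, plan.interval_sd, n)
                months = np.maximum(1.0, np.round(months))
            else:
                months = np.full(n, np.nan)

            emit = active
            frames.append(pd.DataFrame({
                "person_id": pid[emit],
                "wave": w,
                "age": age[emit],
                "state": np.where(alive[emit] & responded[emit],
                                  state[emit], np.nan),
                "alive": alive[emit].astype(int),
                "weight": weight[emit],
                "interval_months": np.where(alive[emit], months[emit], np.nan),
                "responded": (responded[emit]).astype(int),
            }))
            dead_recorded |= ~alive

            if w == plan.waves - 1:
                break

            # fates over the coming interval (independent of the drawn
            # interval length: coefficients are on the per-interval scale)
            idx = np.where(alive)[0]
            if idx.size:
                a_now, s_now = age[idx], state[idx]
                p_surv = truth.p_survive(a_now, s_now)
                _check_probs(p_surv, a_now, s_now, "survival")
                survive = rng.random(idx.size) < p_surv
                p_above = truth.p_above_next(a_now, s_now)
                _check_probs(p_above, a_now, s_now, "transition")
                above = rng.random(idx.size) < p_above
                new_state = np.where(above, 2.0, 1.0)
                state[idx[survive]] = new_state[survive]
                alive[idx[~survive]] = False
            cum_months += months
            age = (baseline + np.round(cum_months / 12.0)).astype(int)

    panel = pd.concat(frames, ignore_index=True)
    panel = panel.sort_values(["person_id", "wave"], kind="stable")
    return panel.reset_index(drop=True)[list(PANEL_COLUMNS)]


def true_rateset(truth: GroundTruth, ages: Sequence[int] | None = None) -> RateSet:
    """Annual rates implied by ``truth``: per-interval probabilities at each
    age annualized with the owning segment's nominal interval (the same
    constant-hazard conversion the estimator applies), so this is the exact
    recovery target for the estimation pipeline."""
    if ages is None:
        ages = range(truth.segments[0].age_lo, truth.segments[-1].age_hi + 1)
    ages = np.asarray(list(ages), dtype=int)
    s1 = np.empty(ages.size)
    s2 = np.empty(ages.size)
    t21 = np.empty(ages.size)
    t22 = np.empty(ages.size)
    for i, a in enumerate(ages):
        seg = truth.segment_for(a)
        k = 12.0 / seg.interval_months
        s1[i] = float(truth.p_survive(a, 1)[0]) ** k
        s2[i] = float(truth.p_survive(a, 2)[0]) ** k
        stay_below = (1.0 - float(truth.p_above_next(a, 1)[0])) ** k
        stay_above = float(truth.p_above_next(a, 2)[0]) ** k
        t21[i] = 1.0 - stay_below
        t22[i] = stay_above
    seams = tuple(s.age_hi for s in truth.segments[:-1])
    return RateSet.from_arrays(ages, s1, s2, t21, t22, seams=seams,
                               label=truth.label)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

# Annual-scale anchor probabilities (value at segment age_lo, value at age_hi)
# for each threshold multiple of the official poverty line.  Chosen once to
# emulate the qualitative demography of US poverty dynamics: small survival
# disparities at young ages that widen to ~0.02 in the 70s with a late-old-age
# crossover near 90; poverty-exit probabilities that decline with age; stasis
# above the threshold that strengthens to mid-age and erodes afterwards, more
# steeply for higher thresholds.
_DEFAULT_ANCHORS: dict[str, dict[str, dict[str, tuple]]] = {
    "1x": {
        "youth_annual":   {"s1": (0.9985, 0.9978), "s2": (0.9990, 0.9986),
                           "t21": (0.42, 0.33), "t22": (0.955, 0.962)},
        "youth_biennial": {"s1": (0.9975, 0.9940), "s2": (0.9983, 0.9962),
                           "t21": (0.32, 0.22), "t22": (0.963, 0.968)},
        "older_biennial": {"s1": (0.9900, 0.700), "s2": (0.9950, 0.680),
                           "t21": (0.20, 0.08), "t22": (0.975, 0.968)},
    },
    "2x": {
        "youth_annual":   {"s1": (0.9986, 0.9980), "s2": (0.9990, 0.9986),
                           "t21": (0.30, 0.24), "t22": (0.915, 0.925)},
        "youth_biennial": {"s1": (0.9977, 0.9945), "s2": (0.9983, 0.9963),
                           "t21": (0.23, 0.17), "t22": (0.930, 0.950)},
        "older_biennial": {"s1": (0.9920, 0.705), "s2": (0.9955, 0.685),
                           "t21": (0.15, 0.05), "t22": (0.952, 0.900)},
    },
    "3x": {
        "youth_annual":   {"s1": (0.9987, 0.9981), "s2": (0.9991, 0.9987),
                           "t21": (0.22, 0.18), "t22": (0.880, 0.895)},
        "youth_biennial": {"s1": (0.9978, 0.9948), "s2": (0.9984, 0.9965),
                           "t21": (0.17, 0.12), "t22": (0.900, 0.935)},
        "older_biennial": {"s1": (0.9930, 0.710), "s2": (0.9960, 0.690),
                           "t21": (0.12, 0.04), "t22": (0.935, 0.850)},
    },
}

THRESHOLDS = tuple(_DEFAULT_ANCHORS)


def default_truth(threshold: str = "1x") -> GroundTruth:
    """Default ground truth for a threshold multiple ("1x", "2x", "3x").

    Anchors are specified on the annual scale and converted to each segment's
    per-interval scale via the constant-hazard compounding that inverts
    :func:`povdyn.rates.annualize`, so the implied annual rates pass exactly
    through the anchors.
    """
    if threshold not in _DEFAULT_ANCHORS:
        raise KeyError(f"unknown threshold {threshold!r}; "
                       f"expected one of {THRESHOLDS}")
    coefs: dict[str, SegmentCoefficients] = {}
    for seg in DEFAULT_SEGMENTS:
        a = _DEFAULT_ANCHORS[threshold][seg.name]
        k = seg.interval_months / 12.0  # annual -> interval compounding
        surv = _anchored_coefficients(
            seg.age_lo, seg.age_hi,
            p_below=tuple(p ** k for p in a["s1"]),
            p_above=tuple(p ** k for p in a["s2"]))
        # transition outcome is "above at next wave": from below that is the
        # exit probability, from above the stay probability
        trans = _anchored_coefficients(
            seg.age_lo, seg.age_hi,
            p_below=tuple(1.0 - (1.0 - p) ** k for p in a["t21"]),
            p_above=tuple(p ** k for p in a["t22"]))
        coefs[seg.name] = SegmentCoefficients(surv, trans)
    return GroundTruth(coefs, DEFAULT_SEGMENTS, label=threshold)


def default_design(scale: float = 1.0) -> PanelDesign:
    """Default wave plans sized like the source panels (roughly 10^5 pooled
    observation pairs per segment at scale 1)."""
    def n(base):
        return max(1, int(round(base * scale)))
    return PanelDesign(plans=(
        WavePlan(DEFAULT_SEGMENTS[0], n(10_100), 12, 1.5),
        WavePlan(DEFAULT_SEGMENTS[1], n(14_000), 9, 2.0),
        WavePlan(DEFAULT_SEGMENTS[2], n(30_000), 6, 2.0, staggered=True),
    ))


def recovery_design(scale: float = 1.0) -> PanelDesign:
    """Design for parameter-recovery validation: the default wave plans sized
    to ~10^5 in-range pooled pairs per segment, with constant weights and full
    response, so recovery error reflects only the estimator's own sampling
    variability."""
    def n(base):
        return max(1, int(round(base * scale)))
    return PanelDesign(plans=(
        WavePlan(DEFAULT_SEGMENTS[0], n(9_100), 12, 1.5),
        WavePlan(DEFAULT_SEGMENTS[1], n(12_500), 9, 2.0),
        WavePlan(DEFAULT_SEGMENTS[2], n(22_400), 6, 2.0, staggered=True),
    ), nonresponse=0.0, weight_sigma=0.0)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[list(PANEL_COLUMNS)].to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel CSV missing columns {missing}")
    return panel[list(PANEL_COLUMNS)]
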