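"""Pooled-panel estimation of annual survival and transition probabilities.

The estimator follows the pooled repeated-observations design: every pair of
consecutive responded interview waves of every person contributes one row with
predictors (age at the first wave, income state at the first wave) and
outcomes (survival to the second wave; income state at the second wave,
conditional on survival and response).  Weighted logistic regressions are fit
separately per age segment -- survey panels with different wave spacings must
not be mixed on one interval scale -- then fitted per-interval probabilities
are converted to annual rates with a constant-hazard root and concatenated
over the full age range.

Logistic fits are weighted maximum likelihood via :mod:`statsmodels` GLM with
a binomial family; standard errors are the usual weighted-likelihood ones (no
design-based replicate-weight variance).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .rates import (DEFAULT_SEGMENTS, RateSet, Segment, annualize_survival,
                    annualize_transition_matrix)

__all__ = [
    "EstimationError",
    "SeparationError",
    "AgeRangeError",
    "Formula",
    "FittedCoefficients",
    "SegmentFit",
    "pool",
    "fit_survival",
    "fit_transition",
    "predict_interval_probability",
    "concatenate_segments",
    "estimate_rateset",
    "nonresponse_by_state_age",
    "fits_to_json",
    "fits_from_json",
]


class EstimationError(RuntimeError):
    """Estimation cannot proceed (empty data, degenerate weights, ...)."""


class SeparationError(EstimationError):
    """The logistic likelihood is unbounded (perfect separation)."""


class AgeRangeError(EstimationError, KeyError):
    """Prediction requested outside the fitted age range."""


@dataclass(frozen=True)
class Formula:
    """Regression specification: polynomial degree in age and whether the
    age(-linear) slope interacts with current state."""

    degree: int = 1
    interaction: bool = True

    def __post_init__(self):
        if self.degree not in (1, 2):
            raise ValueError("age polynomial degree must be 1 or 2")

    @property
    def names(self) -> tuple[str, ...]:
        out = ["const", "age", "above"]
        if self.interaction:
            out.append("age:above")
        if self.degree == 2:
            out.append("age2")
        return tuple(out)

    def design(self, age, above) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        above = np.asarray(above, dtype=float)
        cols = [np.ones_like(age), age, above]
        if self.interaction:
            cols.append(age * above)
        if self.degree == 2:
            cols.append(age ** 2)
        return np.column_stack(cols)


@dataclass
class FittedCoefficients:
    """Logistic coefficients for one outcome on one segment's interval scale."""

    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...]
    formula: Formula
    outcome: str                 # "survival" or "transition"
    segment_name: str
    age_lo: int
    age_hi: int
    mean_interval_months: float
    n_obs: int

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.bse = np.asarray(self.bse, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("coefficient covariance must be symmetric")

    def linear_predictor(self, age, state) -> np.ndarray:
        X = self.formula.design(np.asarray(age, dtype=float),
                                (np.asarray(state) == 2).astype(float))
        return X @ self.params

    def predict(self, age, state) -> np.ndarray:
        """Per-interval probability at (age, state), without range checks."""
        return expit(self.linear_predictor(age, state))

    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "cov": self.cov.tolist(),
            "names": list(self.names),
            "formula": {"degree": self.formula.degree,
                        "interaction": self.formula.interaction},
            "outcome": self.outcome,
            "segment_name": self.segment_name,
            "age_lo": self.age_lo,
            "age_hi": self.age_hi,
            "mean_interval_months": self.mean_interval_months,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCoefficients":
        formula = Formula(int(d["formula"]["degree"]),
                          bool(d["formula"]["interaction"]))
        return cls(np.asarray(d["params"]), np.asarray(d["bse"]),
                   np.asarray(d["cov"]), tuple(d["names"]), formula,
                   d["outcome"], d["segment_name"], int(d["age_lo"]),
                   int(d["age_hi"]), float(d["mean_interval_months"]),
                   int(d["n_obs"]))


@dataclass
class SegmentFit:
    """Survival and transition fits for one segment."""

    survival: FittedCoefficients
    transition: FittedCoefficients

    def __post_init__(self):
        if self.survival.segment_name != self.transition.segment_name:
            raise ValueError("survival and transition fits belong to "
                             "different segments")

    @property
    def age_lo(self) -> int:
        return self.survival.age_lo

    @property
    def age_hi(self) -> int:
        return self.survival.age_hi

    @property
    def name(self) -> str:
        return self.survival.segment_name


def pool(panel: pd.DataFrame) -> pd.DataFrame:
    """Pool consecutive responded wave pairs into one row per pair.

    A pair (t, t+i) is usable when the person responded while alive at t and,
    at the next scheduled wave, is either known dead (survival outcome 0) or
    responded (survival 1 and state observed).  Alive non-response at the
    second wave drops the pair entirely; later pairs of the same person are
    kept.
    """
    df = panel.sort_values(["person_id", "wave"], kind="stable")
    g = df.groupby("person_id", sort=False)
    nxt = {c: g[c].shift(-1) for c in ("wave", "alive", "responded", "state")}

    at_t = (df["responded"] == 1) & (df["alive"] == 1) & df["state"].notna()
    consecutive = nxt["wave"] == df["wave"] + 1
    outcome_known = (nxt["alive"] == 0) | (nxt["responded"] == 1)
    usable = at_t & consecutive & outcome_known

    out = pd.DataFrame({
        "person_id": df.loc[usable, "person_id"].to_numpy(),
        "age": df.loc[usable, "age"].astype(int).to_numpy(),
        "state": df.loc[usable, "state"].astype(int).to_numpy(),
        "survived": nxt["alive"][usable].astype(int).to_numpy(),
        "next_state": nxt["state"][usable].to_numpy(),
        "interval_months": df.loc[usable, "interval_months"].to_numpy(),
        "weight": df.loc[usable, "weight"].to_numpy(),
    })
    if out.empty:
        raise EstimationError("no usable observation pairs in panel")
    return out.reset_index(drop=True)


def _restrict_to_segment(pooled: pd.DataFrame,
                         segment: Segment | None) -> tuple[pd.DataFrame, int, int, str]:
    if segment is None:
        sub = pooled
        lo, hi = int(sub["age"].min()), int(sub["age"].max())
        name = "all"
    else:
        sub = pooled[(pooled["age"] >= segment.age_lo)
                     & (pooled["age"] <= segment.age_hi)]
        lo, hi, name = segment.age_lo, segment.age_hi, segment.name
    if sub.empty:
        raise EstimationError(f"no pooled observations in segment {name}")
    return sub, lo, hi, name


def _fit_glm(y: np.ndarray, X: np.ndarray, w: np.ndarray,
             names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise EstimationError("weights must be positive and finite")
    if y.min() == y.max():
        raise SeparationError(
            "outcome has no variation (all "
            f"{'events' if y.min() else 'non-events'}); the logistic "
            "likelihood is unbounded")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial(),
                         var_weights=w).fit()
    except PerfectSeparationError as err:
        raise SeparationError(f"perfect separation detected: {err}") from err
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    # a sane fit on these data has |coef| of a few units and SEs well under 1;
    # a likelihood drifting to a boundary leaves huge coefficients and/or SEs
    if (np.any(~np.isfinite(params)) or np.any(~np.isfinite(bse))
            or np.max(np.abs(params)) > 50.0 or np.max(bse) > 50.0):
        raise SeparationError(
            "fit diverged (coefficients "
            f"{dict(zip(names, np.round(params, 2)))}); data are separated "
            "or degenerate")
    return params, bse, np.asarray(res.cov_params())


def _fit(pooled: pd.DataFrame, outcome: str, formula: Formula,
         segment: Segment | None) -> FittedCoefficients:
    sub, lo, hi, name = _restrict_to_segment(pooled, segment)
    if outcome == "survival":
        y = sub["survived"].to_numpy(dtype=float)
    else:
        sub = sub[(sub["survived"] == 1) & sub["next_state"].notna()]
        if sub.empty:
            raise EstimationError(
                f"no surviving responded pairs in segment {name}")
        y = (sub["next_state"].to_numpy() == 2).astype(float)
    X = formula.design(sub["age"], (sub["state"] == 2).astype(float))
    w = sub["weight"].to_numpy(dtype=float)
    params, bse, cov = _fit_glm(y, X, w, formula.names)
    months = sub["interval_months"].to_numpy(dtype=float)
    ok = np.isfinite(months)
    mean_i = float(np.average(months[ok], weights=w[ok])) if ok.any() else 12.0
    return FittedCoefficients(params, bse, cov, formula.names, formula,
                              outcome, name, lo, hi, mean_i, len(sub))


def fit_survival(pooled: pd.DataFrame, formula: Formula = Formula(),
                 segment: Segment | None = None) -> FittedCoefficients:
    """Weighted logistic fit of survival to the next wave on (age, state)."""
    return _fit(pooled, "survival", formula, segment)


def fit_transition(pooled: pd.DataFrame, formula: Formula = Formula(),
                   segment: Segment | None = None) -> FittedCoefficients:
    """Weighted logistic fit of being above threshold at the next wave,
    among pairs that survived and responded."""
    return _fit(pooled, "transition", formula, segment)


def predict_interval_probability(coefs: FittedCoefficients, age,
                                 state) -> float | np.ndarray:
    """Inverse-logit of the fitted linear predictor; refuses extrapolation
    outside the segment's fitted age range."""
    ages = np.atleast_1d(np.asarray(age))
    if np.any(ages < coefs.age_lo) or np.any(ages > coefs.age_hi):
        raise AgeRangeError(
            f"age {age} outside fitted range "
            f"[{coefs.age_lo}, {coefs.age_hi}] of segment "
            f"{coefs.segment_name}")
    p = np.asarray(expit(coefs.linear_predictor(age, state))).ravel()
    return float(p[0]) if np.ndim(age) == 0 else p


def concatenate_segments(fits: Sequence[SegmentFit],
                         ages: Sequence[int] | None = None,
                         annualization: str = "probability") -> RateSet:
    """Evaluate each age from its owning segment's fit, annualize with that
    segment's mean observed interval, and concatenate into one RateSet.

    A boundary age covered by two fits belongs to the younger one.  Seam ages
    (the last age of each non-terminal segment) are recorded for plotting.
    """
    fits = sorted(fits, key=lambda f: f.age_lo)
    if ages is None:
        ages = range(min(f.age_lo for f in fits),
                     max(f.age_hi for f in fits) + 1)
    ages = np.asarray(list(ages), dtype=int)

    missing = [int(a) for a in ages
               if not any(f.age_lo <= a <= f.age_hi for f in fits)]
    if missing:
        raise EstimationError(f"segments do not cover ages {missing}")

    s1 = np.empty(ages.size)
    s2 = np.empty(ages.size)
    t21 = np.empty(ages.size)
    t22 = np.empty(ages.size)
    owner_hi: list[int] = []
    for i, a in enumerate(ages):
        fit = next(f for f in fits if f.age_lo <= a <= f.age_hi)
        owner_hi.append(fit.age_hi)
        mi = fit.survival.mean_interval_months
        s1[i] = annualize_survival(
            predict_interval_probability(fit.survival, a, 1), mi)
        s2[i] = annualize_survival(
            predict_interval_probability(fit.survival, a, 2), mi)
        exit_i = predict_interval_probability(fit.transition, a, 1)
        stay_i = predict_interval_probability(fit.transition, a, 2)
        mt = fit.transition.mean_interval_months
        if annualization == "probability":
            t21[i] = 1.0 - annualize_survival(1.0 - exit_i, mt)
            t22[i] = annualize_survival(stay_i, mt)
        elif annualization == "matrix":
            T = np.array([[1.0 - exit_i, 1.0 - stay_i],
                          [exit_i, stay_i]])
            A = annualize_transition_matrix(T, mt)
            t21[i], t22[i] = A[1, 0], A[1, 1]
        else:
            raise ValueError("annualization must be 'probability' or 'matrix'")

    seams = tuple(sorted({int(h) for h in owner_hi if h < int(ages.max())}))
    return RateSet.from_arrays(ages, s1, s2, t21, t22, seams=seams)


def estimate_rateset(panel: pd.DataFrame,
                     segments: Sequence[Segment] = DEFAULT_SEGMENTS,
                     formula: Formula = Formula(),
                     ages: Sequence[int] | None = None,
                     annualization: str = "probability",
                     ) -> tuple[RateSet, list[SegmentFit]]:
    """Full pipeline: pool pairs, fit per segment, annualize, concatenate."""
    pooled = pool(panel)
    fits = [SegmentFit(fit_survival(pooled, formula, seg),
                       fit_transition(pooled, formula, seg))
            for seg in segments]
    rates = concatenate_segments(fits, ages=ages, annualization=annualization)
    return rates, fits


def nonresponse_by_state_age(panel: pd.DataFrame) -> pd.DataFrame:
    """Next-wave non-response proportions by current age and state.

    For each age ``x``: among responders at ``x`` who are *alive at the next
    scheduled wave* (the deceased are removed from the denominators), the
    proportion who do not respond at that wave, separately by state at ``x``,
    plus the between-state difference.  Empty cells are reported as missing.
    """
    df = panel.sort_values(["person_id", "wave"], kind="stable")
    g = df.groupby("person_id", sort=False)
    next_wave = g["wave"].shift(-1)
    next_alive = g["alive"].shift(-1)
    next_resp = g["responded"].shift(-1)

    at_risk = ((df["responded"] == 1) & (df["alive"] == 1)
               & df["state"].notna()
               & (next_wave == df["wave"] + 1) & (next_alive == 1))
    sub = pd.DataFrame({
        "age": df.loc[at_risk, "age"].astype(int),
        "state": df.loc[at_risk, "state"].astype(int),
        "nonresponse": (next_resp[at_risk] == 0).astype(float),
    })
    tab = (sub.groupby(["age", "state"])["nonresponse"]
           .agg(["mean", "size"]).unstack("state"))
    ages = tab.index.to_numpy()

    def col(frame, which, state):
        key = (which, state)
        if key in frame.columns:
            return frame[key].to_numpy(dtype=float)
        return np.full(len(frame), np.nan)

    out = pd.DataFrame({
        "age": ages,
        "p_nonresponse_below": col(tab, "mean", 1),
        "p_nonresponse_above": col(tab, "mean", 2),
        "n_below": col(tab, "size", 1),
        "n_above": col(tab, "size", 2),
    })
    out["difference"] = (out["p_nonresponse_below"]
                         - out["p_nonresponse_above"])
    return out.reset_index(drop=True)


def segment_fits_from_truth(truth) -> list[SegmentFit]:
    """Wrap known per-interval logit coefficients (a
    :class:`~povdyn.synthetic.GroundTruth`) as SegmentFit objects, so the
    model can be parameterized from coefficient tables without any panel.
    Standard errors are zero (the coefficients are taken as given)."""
    fits = []
    for seg in truth.segments:
        sc = truth.coefficients[seg.name]
        parts = {}
        for outcome, coefs in (("survival", sc.survival),
                               ("transition", sc.transition)):
            degree = 2 if coefs[4] != 0.0 else 1
            formula = Formula(degree=degree, interaction=True)
            params = (np.concatenate([coefs[:4], coefs[4:5]])
                      if degree == 2 else coefs[:4])
            k = params.size
            parts[outcome] = FittedCoefficients(
                params, np.zeros(k), np.zeros((k, k)), formula.names, formula,
                outcome, seg.name, seg.age_lo, seg.age_hi,
                seg.interval_months, 0)
        fits.append(SegmentFit(parts["survival"], parts["transition"]))
    return fits


def fits_to_json(fits: Sequence[SegmentFit], path) -> None:
    payload = [{"survival": f.survival.to_dict(),
                "transition": f.transition.to_dict()} for f in fits]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def fits_from_json(path) -> list[SegmentFit]:
    """Load segment fits from JSON, e.g. published coefficient tables, so the
    model can be parameterized without any panel data."""
    with open(path) as fh:
        payload = json.load(fh)
    return [SegmentFit(FittedCoefficients.from_dict(d["survival"]),
                       FittedCoefficients.from_dict(d["transition"]))
            for d in payload]
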