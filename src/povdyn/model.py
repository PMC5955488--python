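"""Statsmodels-style front end: a model bound to panel data, a results object
carrying estimates and chain analyses.

Typical use::

    panel = synthetic.generate_panel(truth, design, seed=1)
    res = PovertyDynamicsModel(panel).fit()
    print(res.summary())
    lt = res.life_table()                  # expectancy / years below / variance
    traj = res.simulate(n=10_000, seed=2)  # individual trajectories

A model can also be parameterized directly from published coefficient tables
(no panel data) via :meth:`PovertyDynamicsModel.from_coefficients`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimation, fundamental, markov, simulation
from .estimation import Formula, SegmentFit
from .rates import DEFAULT_SEGMENTS, RateSet, Segment

__all__ = ["PovertyDynamicsModel", "PovertyDynamicsResults"]

#: Initial below-threshold counts per million used for the standard
#: convergence diagnostic (five cohorts spanning 3%-97% below).
CONVERGENCE_COHORTS = (970_000, 750_000, 500_000, 250_000, 30_000)


class PovertyDynamicsModel:
    """Two-state (below/above an income threshold) age-structured Markov model
    estimated from a longitudinal panel.

    Parameters
    ----------
    panel : DataFrame
        Person-wave observations (columns ``person_id, wave, age, state,
        alive, weight, interval_months, responded``).
    segments : sequence of Segment
        Age segments fitted separately (different interview spacings).
    formula : Formula
        Age polynomial degree and state-interaction flag for both logistic
        regressions.
    annualization : str
        ``"probability"`` (constant-hazard root per probability, default) or
        ``"matrix"`` (root of the joint 2x2 conditional transition matrix).
    """

    def __init__(self, panel: pd.DataFrame | None,
                 segments: Sequence[Segment] = DEFAULT_SEGMENTS,
                 formula: Formula = Formula(),
                 annualization: str = "probability"):
        self.panel = panel
        self.segments = tuple(segments)
        self.formula = formula
        self.annualization = annualization
        self._fits: list[SegmentFit] | None = None

    @classmethod
    def from_csv(cls, path, **kwargs) -> "PovertyDynamicsModel":
        from .synthetic import read_panel
        return cls(read_panel(path), **kwargs)

    @classmethod
    def from_coefficients(cls, fits: Sequence[SegmentFit] | str,
                          annualization: str = "probability",
                          ) -> "PovertyDynamicsModel":
        """Parameterize from fitted coefficients (a list of SegmentFit or a
        JSON path), bypassing panel estimation entirely."""
        if isinstance(fits, (str, bytes)) or hasattr(fits, "__fspath__"):
            fits = estimation.fits_from_json(fits)
        segs = tuple(Segment(f.name, f.age_lo, f.age_hi,
                             f.survival.mean_interval_months) for f in fits)
        model = cls(None, segments=segs, annualization=annualization)
        model._fits = list(fits)
        return model

    def fit(self, ages: Sequence[int] | None = None) -> "PovertyDynamicsResults":
        """Estimate (or evaluate pre-supplied) coefficients and assemble the
        annual rate set over the segments' age range."""
        if self._fits is not None:
            fits = self._fits
            rates = estimation.concatenate_segments(
                fits, ages=ages, annualization=self.annualization)
        else:
            if self.panel is None:
                raise ValueError("model has neither panel data nor "
                                 "pre-supplied coefficients")
            rates, fits = estimation.estimate_rateset(
                self.panel, segments=self.segments, formula=self.formula,
                ages=ages, annualization=self.annualization)
        return PovertyDynamicsResults(self, rates, fits)


@dataclass
class PovertyDynamicsResults:
    """Fitted rates plus every chain-derived quantity.

    All matrix analyses use the restricted grid (first fitted age through age
    100, oldest fitted rates held constant past the data range; the terminal
    age class dies at the next step).  Cohort-projection diagnostics use the
    full 0-100 grid, clamp-padded at young ages, so projections start from
    birth.
    """

    model: PovertyDynamicsModel
    rates: RateSet
    fits: list[SegmentFit] = field(default_factory=list)
    terminal_age: int = 100

    # -- matrices ----------------------------------------------------------
    def L(self, full_grid: bool = False) -> markov.AgeStateMatrix:
        ages = range(0 if full_grid else int(self.rates.ages.min()),
                     self.terminal_age + 1)
        return markov.assemble_L(self.rates, ages=ages, padding="clamp")

    def fundamental_matrix(self, full_grid: bool = False) -> np.ndarray:
        return fundamental.fundamental_matrix(self.L(full_grid))

    # -- life-table quantities ----------------------------------------------
    def life_table(self, ages=None,
                   include_current: bool = True) -> pd.DataFrame:
        if ages is None:
            ages = self.rates.ages
        return fundamental.life_table(self.L(), ages=ages,
                                      include_current=include_current)

    def expectancy(self, age: int, state: int,
                   include_current: bool = True) -> float:
        L = self.L()
        N = fundamental.fundamental_matrix(L)
        return fundamental.remaining_life_expectancy(
            L, N, (age, state), include_current)

    # -- cohort state structure ----------------------------------------------
    def state_structure(self, ages=None) -> pd.DataFrame:
        """Quasi-stable below-threshold share per age: the dominant
        eigenvector of the cumulative unconditional transition product, plus
        the damping ratio of the conditional product (convergence speed)."""
        if ages is None:
            ages = self.rates.ages
        ages = np.asarray(list(ages), dtype=int)
        first = int(self.rates.ages.min())
        rows = []
        Qcum = np.eye(2)
        Tcum = np.eye(2)
        age_cursor = first
        for a in np.sort(ages):
            while age_cursor <= a:
                Qcum = markov.build_Q(self.rates, age_cursor,
                                      padding="clamp") @ Qcum
                Tcum = markov.conditional_T(self.rates, age_cursor,
                                            padding="clamp") @ Tcum
                age_cursor += 1
            qsd = markov.quasi_stable_distribution(Qcum)
            rows.append({"age": int(a), "proportion_below": qsd[0],
                         "damping_ratio": markov.damping_ratio(Tcum)})
        return pd.DataFrame(rows)

    def convergence_table(self, below_counts=CONVERGENCE_COHORTS,
                          total: int = 1_000_000,
                          through_age: int | None = None) -> pd.DataFrame:
        """Project cohorts with different initial below-shares from birth and
        report, per age, each cohort's below-share next to the quasi-stable
        share (the Fig.-3-style convergence diagnostic)."""
        if through_age is None:
            through_age = int(self.rates.ages.max())
        ages = np.arange(0, through_age + 1)
        # a cohort starting at age 0 projected with L sits entirely in the
        # age-a cells after a steps, so the 2-vector recursion v <- Q(a) v is
        # the exact projection restricted to the live block
        cohorts = {b: np.array([b, total - b], dtype=float)
                   for b in below_counts}
        qsd_below = [np.nan]          # identity product at birth: undefined
        shares = {b: [v[0] / v.sum()] for b, v in cohorts.items()}
        Qcum = np.eye(2)
        for a in ages[:-1]:
            Qa = markov.build_Q(self.rates, int(a), padding="clamp")
            Qcum = Qa @ Qcum
            qsd_below.append(markov.quasi_stable_distribution(Qcum)[0])
            for b in below_counts:
                cohorts[b] = Qa @ cohorts[b]
                v = cohorts[b]
                shares[b].append(v[0] / v.sum() if v.sum() > 0 else np.nan)
        out = {"age": ages}
        for b in below_counts:
            out[f"below_start_{b}"] = shares[b]
        out["quasi_stable"] = qsd_below
        return pd.DataFrame(out)

    # -- simulation -----------------------------------------------------------
    def simulate(self, n: int = 10_000, seed: int = 0,
                 start_age: int | None = None,
                 initial_below: float | None = None) -> simulation.TrajectorySet:
        if start_age is None:
            start_age = int(self.rates.ages.min())
        return simulation.simulate_cohort(
            self.rates, n, start_age=start_age,
            initial_below=initial_below, seed=seed,
            terminal_age=self.terminal_age)

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Poverty dynamics age-by-state Markov model",
                 "=" * 60]
        label = self.rates.label or "(unlabelled)"
        lines.append(f"Threshold: {label}   ages "
                     f"{self.rates.ages.min()}-{self.rates.ages.max()}   "
                     f"seams at {list(self.rates.seams)}")
        for fit in self.fits:
            for coefs in (fit.survival, fit.transition):
                lines.append("")
                lines.append(f"[{coefs.segment_name}] ages "
                             f"{coefs.age_lo}-{coefs.age_hi}  "
                             f"outcome={coefs.outcome}  "
                             f"n={coefs.n_obs}  mean interval="
                             f"{coefs.mean_interval_months:.1f} mo")
                tab = pd.DataFrame({
                    "coef": coefs.params,
                    "std err": coefs.bse,
                    "z": coefs.params / np.where(coefs.bse > 0,
                                                 coefs.bse, np.nan),
                }, index=list(coefs.names))
                lines.append(tab.to_string(float_format=lambda v: f"{v: .5f}"))
        lt = self.life_table()
        first = int(self.rates.ages.min())
        sel = lt[lt["age"] == first].set_index("state")
        lines.append("")
        lines.append(f"Remaining life expectancy at age {first}: "
                     f"below={sel.loc[1, 'expectancy']:.2f} y, "
                     f"above={sel.loc[2, 'expectancy']:.2f} y")
        lines.append(f"Expected remaining years below threshold at age "
                     f"{first}: below={sel.loc[1, 'years_below']:.2f} y, "
                     f"above={sel.loc[2, 'years_below']:.2f} y")
        return "\n".join(lines)
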