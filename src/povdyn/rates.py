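"""Annual transition-rate containers and interval-to-annual conversion.

The model is a discrete-age (1-year), two-state Markov chain.  State 1 is
*below* an income threshold, state 2 is *above* it.  Four age-indexed annual
probabilities parameterize everything downstream:

``s1(x)``  probability that an individual below the threshold at age ``x``
           survives to age ``x + 1``;
``s2(x)``  the same for an individual above the threshold;
``t21(x)`` probability, conditional on survival, of exiting the below state
           (moving 1 -> 2) by age ``x + 1``;
``t22(x)`` probability, conditional on survival, of staying above (2 -> 2).

The complements ``t11 = 1 - t21`` (stay below) and ``t12 = 1 - t22`` (enter
the below state) are derived, never stored, so they sum to one exactly.

Panel surveys observe fates over irregular interview intervals (roughly 12 or
24 months), so estimated probabilities live on an *interval* scale and must be
converted to 12-month rates before the chain is assembled.  The conversion
here assumes a constant hazard within the interval: the per-interval
"no event" probability is taken to the power ``12 / i`` for an interval of
``i`` months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = [
    "Segment",
    "DEFAULT_SEGMENTS",
    "owning_segment",
    "annualize",
    "annualize_survival",
    "annualize_transition_matrix",
    "RateSet",
]


@dataclass(frozen=True)
class Segment:
    """One age segment of the panel design.

    Ages ``age_lo..age_hi`` (inclusive) are owned by this segment; a boundary
    age shared with the next segment belongs to the younger one.
    ``interval_months`` is the nominal mean spacing between interview waves.
    """

    name: str
    age_lo: int
    age_hi: int
    interval_months: float

    @property
    def ages(self) -> range:
        return range(self.age_lo, self.age_hi + 1)


#: Default three-segment design: a youth panel interviewed annually to age 33,
#: the same panel on a biennial schedule through age 50, and a 50+ biennial
#: retirement panel.  Mean intervals follow the observed wave spacings
#: (12.4 / 24.1 / 23.8 months).
DEFAULT_SEGMENTS: tuple[Segment, ...] = (
    Segment("youth_annual", 22, 33, 12.4),
    Segment("youth_biennial", 34, 50, 24.1),
    Segment("older_biennial", 51, 95, 23.8),
)


def owning_segment(age: int, segments: Sequence[Segment] = DEFAULT_SEGMENTS) -> Segment:
    """Segment that owns ``age``; boundary ages belong to the younger segment."""
    for seg in segments:
        if seg.age_lo <= age <= seg.age_hi:
            return seg
    raise ValueError(
        f"age {age} is not covered by segments "
        f"{[(s.age_lo, s.age_hi) for s in segments]}"
    )


def annualize(p_event, months):
    """Convert a per-interval event probability to an annual one.

    Assumes a constant hazard over the interval: the probability of avoiding
    the event for 12 months is the interval no-event probability raised to
    ``12 / months``.  Identity when ``months == 12``.
    """
    months = np.asarray(months, dtype=float)
    if np.any(months <= 0):
        raise ValueError("interval length must be positive (months > 0)")
    p = np.asarray(p_event, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("event probability must lie in [0, 1]")
    out = 1.0 - (1.0 - p) ** (12.0 / months)
    return out if out.ndim else float(out)


def annualize_survival(s_interval, months):
    """Annual survival from per-interval survival: ``s ** (12 / months)``."""
    months = np.asarray(months, dtype=float)
    if np.any(months <= 0):
        raise ValueError("interval length must be positive (months > 0)")
    s = np.asarray(s_interval, dtype=float)
    out = s ** (12.0 / months)
    return out if out.ndim else float(out)


def annualize_transition_matrix(T_interval: np.ndarray, months: float) -> np.ndarray:
    """Alternative annualization: the ``12/months``-th root of the joint 2x2
    conditional transition matrix (instead of per-probability conversion).

    Uses the real fractional matrix power.  Raises if the root has negative
    entries or non-unit column sums beyond tolerance (embeddability failure).
    """
    if months <= 0:
        raise ValueError("interval length must be positive (months > 0)")
    T = np.asarray(T_interval, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("expected a 2x2 conditional transition matrix")
    A = sla.fractional_matrix_power(T, 12.0 / months)
    A = np.real_if_close(A, tol=1e6)
    if np.iscomplexobj(A) or np.any(A < -1e-9):
        raise ValueError(
            "interval transition matrix has no valid 12-month root; "
            "use the per-probability annualization instead"
        )
    A = np.clip(np.real(A), 0.0, 1.0)
    # restore exact column stochasticity lost to clipping/rounding
    A /= A.sum(axis=0, keepdims=True)
    return A


@dataclass
class RateSet:
    """Annual survival and transition probabilities on an integer age grid.

    Stored columns are ``s1, s2, t21, t22``; the complements ``t11`` and
    ``t12`` are computed on access so each conditional pair sums to 1 exactly.
    ``seams`` records ages where the owning data segment changes (used for
    plotting the segment seams).
    """

    table: pd.DataFrame
    seams: tuple[int, ...] = ()
    label: str = ""
    _REQUIRED = ("s1", "s2", "t21", "t22")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self._REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"RateSet table missing columns {missing}")
        if df.index.name != "age":
            if "age" in df.columns:
                df = df.set_index("age")
            else:
                df.index.name = "age"
        self.table = df[list(self._REQUIRED)].astype(float).sort_index()
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(cls, ages, s1, s2, t21, t22, seams=(), label="") -> "RateSet":
        df = pd.DataFrame(
            {"s1": s1, "s2": s2, "t21": t21, "t22": t22},
            index=pd.Index(np.asarray(ages, dtype=int), name="age"),
        )
        return cls(df, tuple(seams), label)

    @classmethod
    def constant(cls, ages, s1, s2, t21, t22, label="") -> "RateSet":
        ages = np.asarray(list(ages), dtype=int)
        one = np.ones_like(ages, dtype=float)
        return cls.from_arrays(ages, s1 * one, s2 * one, t21 * one, t22 * one,
                               label=label)

    @classmethod
    def from_csv(cls, path) -> "RateSet":
        df = pd.read_csv(path)
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)

    # -- access ------------------------------------------------------------
    @property
    def ages(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def __contains__(self, age: int) -> bool:
        return int(age) in self.table.index

    def _col(self, name: str, age=None):
        col = self.table[name]
        if age is None:
            return col.to_numpy()
        try:
            return float(col.loc[int(age)])
        except KeyError:
            raise KeyError(f"age {age} not in RateSet range "
                           f"[{self.ages.min()}, {self.ages.max()}]") from None

    def s1(self, age=None):
        return self._col("s1", age)

    def s2(self, age=None):
        return self._col("s2", age)

    def t21(self, age=None):
        return self._col("t21", age)

    def t22(self, age=None):
        return self._col("t22", age)

    def t11(self, age=None):
        v = self._col("t21", age)
        return 1.0 - v

    def t12(self, age=None):
        v = self._col("t22", age)
        return 1.0 - v

    def validate(self) -> None:
        vals = self.table.to_numpy()
        if not np.all(np.isfinite(vals)):
            bad = self.table.index[~np.isfinite(vals).all(axis=1)].tolist()
            raise ValueError(f"non-finite rates at ages {bad}")
        if np.any(vals < 0) or np.any(vals > 1):
            bad = self.table.index[((vals < 0) | (vals > 1)).any(axis=1)].tolist()
            raise ValueError(f"rates outside [0, 1] at ages {bad}")

    def clamped(self, age: int) -> dict:
        """Rates at ``age``, holding the youngest/oldest row constant outside
        the fitted range (padding policy for the full 0-100 grid)."""
        a = int(np.clip(age, self.ages.min(), self.ages.max()))
        row = self.table.loc[a]
        return {k: float(row[k]) for k in self._REQUIRED}
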