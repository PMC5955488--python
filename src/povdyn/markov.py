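"""Age-by-state block matrix construction, cohort projection and
eigenstructure of cumulative transition products.

The chain advances a cohort one year of age per step.  Each age ``x`` has a
2x2 unconditional transition block ``Q(x)`` combining state-specific survival
with state switching conditional on survival; cell ``(i, j)`` moves state
``j`` at age ``x`` to state ``i`` at age ``x + 1`` (column-stochastic-style
layout, state 1 = below the income threshold).  Blocks sit on the block
subdiagonal of the full age-state matrix ``L``; the terminal age class maps to
nothing (everyone alive there dies at the next step), which makes ``L``
nilpotent and the chain absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rates import RateSet

__all__ = [
    "QBlock",
    "build_Q",
    "conditional_T",
    "AgeStateMatrix",
    "assemble_L",
    "project_cohort",
    "cumulative_Q",
    "quasi_stable_distribution",
    "damping_ratio",
    "NoDominantEigenvalueError",
]

N_STATES = 2


class NoDominantEigenvalueError(ValueError):
    """Eigenvalues tie in modulus: no strictly dominant eigenvector."""


def _rates_at(rates: RateSet, age: int, padding: str) -> dict:
    if int(age) in rates:
        return {k: float(rates.table.loc[int(age), k])
                for k in ("s1", "s2", "t21", "t22")}
    if padding == "clamp":
        return rates.clamped(int(age))
    raise KeyError(
        f"age {age} outside RateSet range [{rates.ages.min()}, "
        f"{rates.ages.max()}] and padding policy is {padding!r}")


def build_Q(rates: RateSet, x: int, padding: str = "none") -> np.ndarray:
    """Unconditional 2x2 transition block for the step age ``x -> x + 1``:

    ``[[s1*t11, s2*t12], [s1*t21, s2*t22]]`` evaluated at ``x``; column ``j``
    sums to the state-``j`` survival probability.
    """
    r = _rates_at(rates, x, padding)
    t11 = 1.0 - r["t21"]
    t12 = 1.0 - r["t22"]
    return np.array([[r["s1"] * t11, r["s2"] * t12],
                     [r["s1"] * r["t21"], r["s2"] * r["t22"]]])


def conditional_T(rates: RateSet, x: int, padding: str = "none") -> np.ndarray:
    """Conditional (survival excluded) column-stochastic 2x2 block at ``x``."""
    r = _rates_at(rates, x, padding)
    return np.array([[1.0 - r["t21"], 1.0 - r["t22"]],
                     [r["t21"], r["t22"]]])


@dataclass
class QBlock:
    """A per-age block together with its age label (mostly for serialization
    and inspection; the heavy lifting uses plain arrays)."""

    age: int
    matrix: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (N_STATES, N_STATES):
            raise ValueError("Q block must be 2x2")
        if np.any(M < 0) or np.any(M > 1):
            raise ValueError("Q block entries must lie in [0, 1]")
        if np.any(M.sum(axis=0) > 1.0 + 1e-12):
            raise ValueError("Q block column sums exceed 1")
        self.matrix = M


@dataclass
class AgeStateMatrix:
    """The block-subdiagonal age-state matrix ``L`` plus its age grid.

    Cells are ordered age-major: index ``2 * age_index + (state - 1)``.
    With 101 age classes (ages 0-100) and 2 states the matrix is 202 x 202.
    """

    matrix: np.ndarray
    ages: np.ndarray
    state_labels: tuple[str, str] = ("below", "above")

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        n = N_STATES * self.ages.size
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{self.ages.size} age classes x {N_STATES} states")

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def age_index(self, age: int) -> int:
        idx = np.flatnonzero(self.ages == int(age))
        if idx.size == 0:
            raise KeyError(f"age {age} not on the grid "
                           f"[{self.ages.min()}, {self.ages.max()}]")
        return int(idx[0])

    def cell_index(self, age: int, state: int) -> int:
        if state not in (1, 2):
            raise ValueError("state must be 1 (below) or 2 (above)")
        return N_STATES * self.age_index(age) + (state - 1)

    def block(self, from_age: int) -> np.ndarray:
        """The 2x2 block mapping age ``from_age`` to ``from_age + 1``."""
        j = self.age_index(from_age)
        if j + 1 >= self.ages.size:
            raise KeyError(f"age {from_age} is the terminal age class")
        return self.matrix[N_STATES * (j + 1):N_STATES * (j + 2),
                           N_STATES * j:N_STATES * (j + 1)]

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",")

    def meta(self) -> dict:
        return {"ages": self.ages.tolist(),
                "state_labels": list(self.state_labels),
                "convention": "column j = cell at age x; row i = cell at "
                              "age x+1; transitions j -> i"}


def assemble_L(rates: RateSet, ages: Sequence[int] | None = None,
               padding: str = "clamp") -> AgeStateMatrix:
    """Assemble ``L`` with ``Q(x)`` blocks on the block subdiagonal.

    ``ages`` defaults to the full 0-100 grid (202 x 202 with two states).
    Ages outside the rate table are filled per ``padding``: ``"clamp"`` holds
    the youngest/oldest fitted rates constant, ``"none"`` raises.  The last
    age class maps to nothing: everyone alive there dies at the next step.
    """
    if ages is None:
        ages = range(0, 101)
    ages = np.asarray(list(ages), dtype=int)
    if ages.size < 2 or np.any(np.diff(ages) != 1):
        raise ValueError("ages must be a consecutive increasing grid")
    n = N_STATES * ages.size
    L = np.zeros((n, n))
    for k, age in enumerate(ages[:-1]):
        L[N_STATES * (k + 1):N_STATES * (k + 2),
          N_STATES * k:N_STATES * (k + 1)] = build_Q(rates, int(age), padding)
    return AgeStateMatrix(L, ages)


def project_cohort(L: AgeStateMatrix, n0: np.ndarray, x: int) -> np.ndarray:
    """``n(x) = L^x n(0)`` by repeated application (never a dense power)."""
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (L.dim,):
        raise ValueError(f"cohort vector length {n0.shape} does not match "
                         f"matrix dimension {L.dim}")
    if x < 0:
        raise ValueError("number of steps must be >= 0")
    v = n0.copy()
    for _ in range(int(x)):
        v = L.matrix @ v
    return v


def cumulative_Q(rates: RateSet, x: int, first: int | None = None,
                 padding: str = "none") -> np.ndarray:
    """Right-to-left product ``Q(x) Q(x-1) ... Q(first)`` of the per-age
    blocks: the cumulative demographic process from age ``first`` through the
    step starting at age ``x``."""
    if first is None:
        first = int(rates.ages.min())
    if x < first:
        raise ValueError(f"x={x} precedes the first model age {first}")
    M = np.eye(N_STATES)
    for age in range(int(first), int(x) + 1):
        M = build_Q(rates, age, padding) @ M   # left-accumulate
    return M


def _eig2(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigenvalues of a real 2x2 matrix, sorted by modulus
    (descending), plus a right eigenvector of the first."""
    a, b, c, d = M.ravel()
    tr, det = a + d, a * d - b * c
    disc = tr * tr - 4.0 * det
    if disc >= 0:
        root = np.sqrt(disc)
        lam = np.array([(tr + root) / 2.0, (tr - root) / 2.0])
    else:
        root = np.sqrt(-disc) * 1j
        lam = np.array([(tr + root) / 2.0, (tr - root) / 2.0])
    order = np.argsort(-np.abs(lam))
    lam = lam[order]
    l1 = lam[0]
    # rows of (M - l1 I) are proportional; pick the better-conditioned kernel
    v1 = np.array([b, l1 - a])
    v2 = np.array([l1 - d, c])
    v = v1 if np.linalg.norm(v1) >= np.linalg.norm(v2) else v2
    if np.linalg.norm(v) == 0:            # diagonal/defective fallback
        v = np.array([1.0, 0.0]) if abs(a - l1) <= abs(d - l1) \
            else np.array([0.0, 1.0])
    return lam, v


def quasi_stable_distribution(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Normalized dominant right eigenvector of a nonnegative 2x2 matrix:
    the state structure a cohort approaches under repeated application.

    Raises :class:`NoDominantEigenvalueError` when the two eigenvalues tie in
    modulus (no strict dominance), rather than silently picking one.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (N_STATES, N_STATES):
        raise ValueError("expected a 2x2 matrix")
    if np.any(M < 0) or not np.any(M > 0):
        raise ValueError("matrix must be nonnegative and nonzero")
    lam, v = _eig2(M)
    scale = max(abs(lam[0]), 1.0)
    if abs(abs(lam[0]) - abs(lam[1])) <= tol * scale:
        raise NoDominantEigenvalueError(
            f"eigenvalue moduli tie (|{lam[0]:.6g}| vs |{lam[1]:.6g}|); "
            "no strictly dominant eigenvector")
    v = np.real(v)
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9 * max(np.abs(v).max(), 1.0)):
        raise ValueError("dominant eigenvector is not sign-consistent")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def damping_ratio(M: np.ndarray) -> float:
    """``|lambda_1| / |lambda_2|`` of a cumulative *conditional* transition
    matrix: how fast a cohort's state structure converges (larger = faster).
    A rank-deficient matrix (``lambda_2 = 0``) gives ``inf``."""
    M = np.asarray(M, dtype=float)
    if M.shape != (N_STATES, N_STATES):
        raise ValueError("expected a 2x2 matrix")
    lam, _ = _eig2(M)
    if abs(lam[1]) == 0.0:
        return float("inf")
    return float(abs(lam[0]) / abs(lam[1]))
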