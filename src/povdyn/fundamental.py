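"""Absorbing-chain analysis: the fundamental matrix and what it yields.

Appending an absorbing Death state to the age-state matrix ``L`` (mortality
row = 1 minus each column sum) makes the chain column-stochastic.  Because
ages strictly advance, ``L`` is nilpotent, so the fundamental matrix

    N = (I - L)^{-1} = I + L + L^2 + ...

is a finite sum; entry ``(i, j)`` is the expected number of visits to cell
``i`` for an individual starting in cell ``j``, counting the starting visit.
Column sums of ``N`` are remaining life expectancies (in years, counting the
current year); restricting the sum to below-threshold rows gives expected
remaining years below the threshold.  Variances follow the standard factorial
moment identity ``eta2' = eta1' (2N - I)``.

``I - L`` is lower block-triangular with a unit diagonal, so ``N`` is obtained
by a triangular solve (exact back-substitution by age) rather than a general
inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .markov import N_STATES, AgeStateMatrix

__all__ = [
    "AbsorbingChain",
    "build_absorbing_chain",
    "fundamental_matrix",
    "remaining_life_expectancy",
    "expected_years_below",
    "variance_remaining_life",
    "life_table",
]

_TOL = 1e-12


@dataclass
class AbsorbingChain:
    """Column-stochastic chain ``P = [[L, 0], [m, 1]]`` over transient
    (age, state) cells plus one absorbing Death state."""

    L: AgeStateMatrix
    mortality: np.ndarray          # per transient column

    @property
    def P(self) -> np.ndarray:
        n = self.L.dim
        P = np.zeros((n + 1, n + 1))
        P[:n, :n] = self.L.matrix
        P[n, :n] = self.mortality
        P[n, n] = 1.0
        return P


def build_absorbing_chain(L: AgeStateMatrix) -> AbsorbingChain:
    """Mortality row is the column-sum deficit of ``L``; errors if any column
    sum exceeds 1 beyond tolerance (not substochastic)."""
    sums = L.column_sums()
    if np.any(sums > 1.0 + _TOL):
        bad = np.flatnonzero(sums > 1.0 + _TOL)
        raise ValueError(f"columns {bad.tolist()} of L sum to more than 1")
    m = np.clip(1.0 - sums, 0.0, 1.0)
    return AbsorbingChain(L, m)


def fundamental_matrix(L: AgeStateMatrix) -> np.ndarray:
    """``N = (I - L)^{-1}`` via back-substitution by age (``I - L`` is lower
    block-triangular with unit diagonal, so the solve is exact)."""
    A = np.eye(L.dim) - L.matrix
    try:
        N = solve_triangular(A, np.eye(L.dim), lower=True,
                             unit_diagonal=True)
    except np.linalg.LinAlgError as err:   # pragma: no cover - unreachable
        raise ValueError("I - L is singular: the chain has an immortal "
                         "cycle") from err
    return N


def _start_col(L: AgeStateMatrix, N: np.ndarray, start) -> np.ndarray:
    if isinstance(start, tuple):
        j = L.cell_index(*start)
    else:
        j = int(start)
    return N[:, j]


def remaining_life_expectancy(L: AgeStateMatrix, N: np.ndarray, start,
                              include_current: bool = True) -> float:
    """Expected remaining years alive from a starting (age, state) cell: the
    column sum of ``N``.  ``include_current=False`` subtracts the year being
    lived now (the two conventions differ by exactly 1)."""
    eta = float(_start_col(L, N, start).sum())
    return eta if include_current else eta - 1.0


def expected_years_below(L: AgeStateMatrix, N: np.ndarray, start,
                         include_current: bool = True) -> float:
    """Expected remaining years spent below the threshold: the sum of the
    below-state rows of ``N`` in the starting column.  With
    ``include_current=False`` the current year is not counted (subtract 1 only
    when starting below)."""
    col = _start_col(L, N, start)
    below = float(col[0::N_STATES].sum())
    if not include_current:
        if isinstance(start, tuple):
            j = L.cell_index(*start)
        else:
            j = int(start)
        if j % N_STATES == 0:       # starting cell is a below-state cell
            below -= 1.0
    return below


def variance_remaining_life(L: AgeStateMatrix, N: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell mean, variance and CV of remaining lifetime (years, counting
    the current year).

    ``eta1' = 1'N``; second factorial moment ``eta2' = eta1'(2N - I)``;
    ``var = eta2 - eta1**2`` elementwise.  The variance is identical under
    both counting conventions (a shift by 1).
    """
    eta1 = N.sum(axis=0)
    eta2 = eta1 @ (2.0 * N - np.eye(L.dim))
    var = eta2 - eta1 ** 2
    if np.any(var < -1e-9):
        raise ValueError("negative remaining-life variance: inconsistent "
                         "fundamental matrix")
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(eta1 > 0, np.sqrt(var) / eta1, np.nan)
    return eta1, var, cv


def life_table(L: AgeStateMatrix, ages=None,
               include_current: bool = True) -> pd.DataFrame:
    """Per (age, state) summary: remaining life expectancy, expected years
    below the threshold, their ratio, variance and CV of remaining life.

    ``ages`` restricts the output rows (default: every age on the grid except
    the terminal class).  The counting convention is recorded in
    ``df.attrs["include_current"]``.
    """
    N = fundamental_matrix(L)
    eta1, var, cv = variance_remaining_life(L, N)
    if ages is None:
        ages = L.ages[:-1]
    rows = []
    for age in np.asarray(ages, dtype=int):
        for state in (1, 2):
            j = L.cell_index(int(age), state)
            expectancy = eta1[j] - (0.0 if include_current else 1.0)
            below = expected_years_below(L, N, j, include_current)
            rows.append({
                "age": int(age),
                "state": state,
                "expectancy": expectancy,
                "years_below": below,
                "proportion_below": below / expectancy if expectancy > 0
                else np.nan,
                "variance": var[j],
                "cv": cv[j],
            })
    df = pd.DataFrame(rows)
    df.attrs["include_current"] = include_current
    return df
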