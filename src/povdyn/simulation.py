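"""Individual lifetime trajectory simulation and residence-time summaries.

Each simulated individual is one sample path of the age-by-state chain: at
every age the year's fate is drawn in the model's event order -- survival
first (state-specific), then, conditional on survival, next year's income
state.  The cohort of paths exhibits the dynamic heterogeneity the chain
implies: identical individuals (same rates) end up with very different
lifespans and poverty histories purely through stochastic state switching.

Draws are made age-by-age across the whole cohort from a single seeded
generator (age-major stream order), so results are bitwise reproducible for a
fixed seed and cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import cumulative_Q, quasi_stable_distribution
from .rates import RateSet

__all__ = [
    "TrajectorySet",
    "ResidenceSummary",
    "simulate_cohort",
    "residence_summary",
    "survivorship_and_snapshot",
]

DEAD = 0  # state code in the trajectory raster; 1 = below, 2 = above


@dataclass
class TrajectorySet:
    """Simulated cohort: a (n, n_ages) state raster with codes 0 (dead),
    1 (below threshold), 2 (above threshold).

    ``death_age[i]`` is the age at which individual ``i`` is first dead
    (their last year alive is ``death_age - 1``).  Everyone dies by
    ``terminal_age + 1``.
    """

    states: np.ndarray
    start_age: int
    seed: int
    initial_below: float
    rates_label: str = ""

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValueError("states raster must be 2-D (individuals x ages)")

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.states.shape[1])

    @property
    def alive(self) -> np.ndarray:
        return self.states > DEAD

    @property
    def death_age(self) -> np.ndarray:
        """Age at death = last alive age + 1 (death strikes between ages)."""
        return self.start_age + self.alive.sum(axis=1)

    @property
    def lifespan_years(self) -> np.ndarray:
        """Years lived from the start age, counting the starting year."""
        return self.alive.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (individual, age, state) over alive person-years."""
        idx, t = np.nonzero(self.alive)
        return pd.DataFrame({"individual": idx,
                             "age": self.start_age + t,
                             "state": self.states[idx, t]})

    def metadata(self) -> dict:
        return {"n": int(self.n), "seed": int(self.seed),
                "start_age": int(self.start_age),
                "initial_below": float(self.initial_below),
                "rates": self.rates_label}


def simulate_cohort(rates: RateSet, n: int, start_age: int = 22,
                    initial_below: float | None = None, seed: int = 0,
                    terminal_age: int = 100,
                    initial_states: np.ndarray | None = None) -> TrajectorySet:
    """Simulate ``n`` lifetime trajectories from ``start_age``.

    ``initial_below`` is the probability of starting below the threshold;
    ``None`` uses the quasi-stable below-share at the start age (the dominant
    eigenvector of the cumulative transition product up to that age).
    ``initial_states`` overrides the random initial draw with fixed states.
    Ages past the rate table are held at the oldest fitted rates; everyone
    alive at ``terminal_age`` dies at the next step.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ages = np.arange(start_age, terminal_age + 1)
    lo = int(rates.ages.min())
    if start_age < lo:
        raise ValueError(f"start_age {start_age} precedes first rated age {lo}")

    rng = np.random.default_rng(seed)
    if initial_below is None:
        if start_age == lo:
            qsd = quasi_stable_distribution(cumulative_Q(rates, lo))
        else:
            qsd = quasi_stable_distribution(
                cumulative_Q(rates, min(start_age, int(rates.ages.max())),
                             padding="clamp"))
        initial_below = float(qsd[0])
    if not (0.0 <= initial_below <= 1.0):
        raise ValueError("initial_below must lie in [0, 1]")

    states = np.zeros((n, ages.size), dtype=np.int8)
    if initial_states is not None:
        current = np.asarray(initial_states, dtype=np.int8)
        if current.shape != (n,) or not np.all(np.isin(current, (1, 2))):
            raise ValueError("initial_states must be length n with values "
                             "in {1, 2}")
        current = current.copy()
    else:
        current = np.where(rng.random(n) < initial_below, 1, 2).astype(np.int8)
    alive = np.ones(n, dtype=bool)

    for t, age in enumerate(ages):
        states[alive, t] = current[alive]
        if age == terminal_age:
            break
        r = rates.clamped(int(age))
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        s = np.where(current[idx] == 1, r["s1"], r["s2"])
        survive = rng.random(idx.size) < s
        alive[idx[~survive]] = False
        surv_idx = idx[survive]
        if surv_idx.size:
            p_above = np.where(current[surv_idx] == 1,
                               r["t21"], r["t22"])
            above = rng.random(surv_idx.size) < p_above
            current[surv_idx] = np.where(above, 2, 1).astype(np.int8)

    return TrajectorySet(states, start_age, seed, initial_below, rates.label)


@dataclass
class ResidenceSummary:
    """Residence-time and entry/exit-age summaries for the below state.

    Entry = a 2 -> 1 transition between consecutive ages, plus starting below
    at the start age (counted as an entry at that age).  Exit = a 1 -> 2
    transition *or* death while below (exit age = the first age no longer
    below).  Entries and exits alternate within each individual.
    """

    years_below: np.ndarray              # per individual
    entry_ages: np.ndarray               # pooled over individuals
    exit_ages: np.ndarray
    entries_per_individual: np.ndarray
    exits_per_individual: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.years_below.mean())

    @property
    def sd(self) -> float:
        return float(self.years_below.std(ddof=1))

    @property
    def mode(self) -> int:
        """Most common integer years below; ties go to the smaller value."""
        return int(np.bincount(self.years_below.astype(int)).argmax())

    def histogram(self) -> pd.DataFrame:
        counts = np.bincount(self.years_below.astype(int))
        return pd.DataFrame({"years_below": np.arange(counts.size),
                             "individuals": counts})


def residence_summary(traj: TrajectorySet) -> ResidenceSummary:
    """Count per-individual years below threshold and the ages of every entry
    into and exit from the below state (death while below counts as an exit)."""
    S = traj.states
    ages = traj.ages
    below = S == 1
    years_below = below.sum(axis=1)

    prev_below = np.zeros_like(below)
    prev_below[:, 1:] = below[:, :-1]
    # entries: below now, not below one age earlier (start age included)
    entry_mask = below & ~prev_below
    # exits: below one age earlier, not below now (state 2 or dead) ...
    exit_mask = prev_below & ~below
    i_ent, t_ent = np.nonzero(entry_mask)
    i_ext, t_ext = np.nonzero(exit_mask)
    entry_ages = ages[t_ent]
    exit_ages = ages[t_ext].tolist()
    exits_per = np.bincount(i_ext, minlength=traj.n)

    # ... and death at the step after the final grid age while still below
    final_below = below[:, -1]
    if np.any(final_below):
        terminal_exit_age = int(ages[-1]) + 1
        exit_ages.extend([terminal_exit_age] * int(final_below.sum()))
        exits_per = exits_per + final_below.astype(int)

    entries_per = np.bincount(i_ent, minlength=traj.n)
    if np.any((entries_per - exits_per) < 0) or \
            np.any((entries_per - exits_per) > 1):
        raise AssertionError("entry/exit bookkeeping lost alternation")
    return ResidenceSummary(years_below.astype(int),
                            np.sort(entry_ages),
                            np.sort(np.asarray(exit_ages, dtype=int)),
                            entries_per, exits_per)


def survivorship_and_snapshot(traj: TrajectorySet,
                              window: tuple[int, int] = (50, 60),
                              k: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables for the trajectory figure: per-age counts alive by
    state (the survivorship-shaped raster) and a ``k``-individual state
    raster over the age window."""
    if k > traj.n:
        raise ValueError(f"snapshot size k={k} exceeds cohort size {traj.n}")
    lo, hi = window
    ages = traj.ages
    if lo < ages[0] or hi > ages[-1] or lo > hi:
        raise ValueError(f"window {window} outside simulated ages "
                         f"[{ages[0]}, {ages[-1]}]")
    S = traj.states
    counts = pd.DataFrame({
        "age": ages,
        "n_below": (S == 1).sum(axis=0),
        "n_above": (S == 2).sum(axis=0),
    })
    counts["n_alive"] = counts["n_below"] + counts["n_above"]

    sel = (ages >= lo) & (ages <= hi)
    snap = pd.DataFrame(S[:k, sel], columns=ages[sel])
    snap.index.name = "individual"
    return counts, snap
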