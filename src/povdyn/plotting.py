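"""Figure helpers mirroring the standard panel layouts of this analysis:
age-specific rates with segment seams, cohort convergence, expectancy and
variance curves, trajectory rasters, and residence-time histograms.

Every function takes precomputed tables (so figures are regenerable from
saved CSVs without refitting) and returns a matplotlib Figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .rates import RateSet
from .simulation import ResidenceSummary, TrajectorySet

__all__ = [
    "plot_rates",
    "plot_convergence",
    "plot_life_table",
    "plot_variance",
    "plot_trajectories",
    "plot_residence",
]

BELOW_COLOR = "#c0392b"   # red: below threshold
ABOVE_COLOR = "#2255aa"   # blue: above threshold
SEAM_COLOR = "#2e8b57"    # green vertical seam lines


def _seams(ax, seams) -> None:
    for s in seams:
        ax.axvline(s, color=SEAM_COLOR, linestyle="--", linewidth=0.8)


def plot_rates(rates: RateSet, title: str = "") -> plt.Figure:
    """Annual survival (left) and conditional probability of being above the
    threshold next year (right), by current state."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ages = rates.ages
    ax1.plot(ages, rates.s1(), color=BELOW_COLOR, label="below threshold")
    ax1.plot(ages, rates.s2(), color=ABOVE_COLOR, label="above threshold")
    ax1.set(xlabel="age", ylabel="annual survival", title="Survival")
    ax2.plot(ages, rates.t21(), color=BELOW_COLOR,
             label="from below (exit)")
    ax2.plot(ages, rates.t22(), color=ABOVE_COLOR, label="from above (stay)")
    ax2.set(xlabel="age", ylabel="P(above at age x+1 | survive)",
            title="Transitions")
    for ax in (ax1, ax2):
        _seams(ax, rates.seams)
        ax.legend(frameon=False, fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_convergence(table: pd.DataFrame, seams=(33, 50),
                     title: str = "") -> plt.Figure:
    """Below-threshold share of projected cohorts converging onto the
    quasi-stable share (black)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in [c for c in table.columns if c.startswith("below_start_")]:
        ax.plot(table["age"], table[col], color=BELOW_COLOR, linewidth=0.9)
    ax.plot(table["age"], table["quasi_stable"], color="black", linewidth=1.5,
            label="quasi-stable (dominant eigenvector)")
    _seams(ax, seams)
    ax.set(xlabel="age", ylabel="proportion below threshold", title=title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def _by_state(lt: pd.DataFrame, col: str):
    b = lt[lt["state"] == 1].set_index("age")[col]
    a = lt[lt["state"] == 2].set_index("age")[col]
    return b, a


def plot_life_table(lt: pd.DataFrame, seams=(33, 50),
                    title: str = "") -> plt.Figure:
    """Remaining life expectancy and expected years below threshold (left),
    and the below-share of remaining life (right), by state at age x."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for col, style in (("expectancy", "-"), ("years_below", "--")):
        b, a = _by_state(lt, col)
        ax1.plot(b.index, b, style, color=BELOW_COLOR)
        ax1.plot(a.index, a, style, color=ABOVE_COLOR)
    ax1.set(xlabel="age", ylabel="years",
            title="Remaining life (solid) / years below (dashed)")
    b, a = _by_state(lt, "proportion_below")
    ax2.plot(b.index, b, color=BELOW_COLOR, label="below at age x")
    ax2.plot(a.index, a, color=ABOVE_COLOR, label="above at age x")
    ax2.set(xlabel="age", ylabel="proportion of remaining life below",
            title="Share of remaining life below threshold")
    ax2.legend(frameon=False, fontsize=8)
    for ax in (ax1, ax2):
        _seams(ax, seams)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_variance(lt: pd.DataFrame, seams=(33, 50),
                  title: str = "") -> plt.Figure:
    """Variance (left) and coefficient of variation (right) of remaining life."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for col, ax, ylab in (("variance", ax1, "variance (years^2)"),
                          ("cv", ax2, "coefficient of variation")):
        b, a = _by_state(lt, col)
        ax.plot(b.index, b, color=BELOW_COLOR, label="below at age x")
        ax.plot(a.index, a, color=ABOVE_COLOR, label="above at age x")
        ax.set(xlabel="age", ylabel=ylab)
        _seams(ax, seams)
        ax.legend(frameon=False, fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_trajectories(traj: TrajectorySet, counts: pd.DataFrame,
                      snapshot: pd.DataFrame, title: str = "") -> plt.Figure:
    """Whole-cohort state raster (survivorship-curve shaped) and a
    k-individual snapshot over the age window."""
    from matplotlib.colors import ListedColormap
    cmap = ListedColormap(["#27408b", "#74c476", "#c0392b"])  # dead/below/above
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    order = np.argsort(-traj.lifespan_years)
    ax1.imshow(traj.states[order], aspect="auto", cmap=cmap, vmin=0, vmax=2,
               extent=(traj.ages[0], traj.ages[-1] + 1, traj.n, 0),
               interpolation="nearest")
    ax1.set(xlabel="age", ylabel="individual (sorted by lifespan)",
            title=f"cohort of {traj.n}")
    ages = snapshot.columns.to_numpy()
    ax2.imshow(snapshot.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=2,
               extent=(ages[0], ages[-1] + 1, len(snapshot), 0),
               interpolation="nearest")
    ax2.set(xlabel="age", ylabel="individual",
            title=f"snapshot of {len(snapshot)} individuals")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_residence(summary: ResidenceSummary, seams=(33, 50),
                   title: str = "") -> plt.Figure:
    """Histograms of years below threshold and of entry/exit ages."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].hist(summary.years_below,
                 bins=np.arange(summary.years_below.max() + 2) - 0.5,
                 color="#555555")
    axes[0].set(xlabel="years below threshold", ylabel="individuals",
                title=f"mean={summary.mean:.2f}, sd={summary.sd:.2f}, "
                      f"mode={summary.mode}")
    for ax, data, lab in ((axes[1], summary.entry_ages, "age of entry"),
                          (axes[2], summary.exit_ages, "age of exit")):
        if len(data):
            ax.hist(data, bins=np.arange(min(data), max(data) + 2) - 0.5,
                    color="#555555")
        ax.set(xlabel=lab, ylabel="events")
        _seams(ax, seams)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
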