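"""Network-activity statistics: overall frequency, rasters, grouped
histograms and the two-way ANOVA over family sweeps.

The study's excitability readout is the *overall frequency*: the total
number of spikes emitted by all cells of a network configuration during the
simulation divided by the simulation time (spikes per second).  Sweeps are
compared with a two-way ANOVA (factors: newborn fraction and family/type)
using type-II sums of squares so that the unbalanced MPSL1 design (missing
high-fraction cells) is handled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SimResult

__all__ = [
    "overall_frequency",
    "raster",
    "grouped_spike_histogram",
    "two_way_anova",
    "plot_raster",
    "plot_frequency_curves",
]


def overall_frequency(result: SimResult) -> float:
    """Total spike count across all cells divided by simulation time (s⁻¹)."""
    if result.duration <= 0:
        raise ValueError("simulation duration must be positive")
    return result.total_spikes() / (result.duration / 1000.0)


def raster(result: SimResult) -> pd.DataFrame:
    """(cell, time) event table ordered by time, with type/population bands."""
    cells, times = [], []
    for ci, s in enumerate(result.spikes):
        cells.extend([ci] * len(s))
        times.extend(s.tolist())
    df = pd.DataFrame({"cell": cells, "time_ms": times})
    df["cell_type"] = [result.cell_types[c] for c in df.cell]
    df["population"] = [result.populations[c] for c in df.cell]
    return df.sort_values("time_ms", kind="stable").reset_index(drop=True)


def grouped_spike_histogram(result: SimResult, bin_ms: float = 5.0) -> pd.DataFrame:
    """Spike counts per time bin, grouped by GC population (control vs PILO
    vs mature) and interneurons; group sums equal group totals."""
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, result.duration + bin_ms, bin_ms)
    rows = {}
    for ci, s in enumerate(result.spikes):
        if result.cell_types[ci] == "GC":
            group = result.populations[ci] or "mature"
        else:
            group = result.cell_types[ci]
        h, _ = np.histogram(s, bins=edges)
        rows[group] = rows.get(group, np.zeros(len(edges) - 1, dtype=int)) + h
    df = pd.DataFrame(rows)
    df.insert(0, "bin_start_ms", edges[:-1])
    return df


def two_way_anova(table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Two-way ANOVA of overall frequency on (fraction, family) + interaction.

    Type-II sums of squares (statsmodels) to handle unbalanced designs such
    as MPSL1 sweeps with infeasible high fractions.  Returns a table with
    F, p and significance at ``alpha`` for both main effects and the
    interaction.  Requires >= 2 levels per factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.dropna(subset=["overall_frequency"]).copy()
    if df["family"].nunique() < 2 or df["fraction"].nunique() < 2:
        raise ValueError("two_way_anova requires >= 2 levels per factor")
    df["fraction"] = df["fraction"].astype(str)  # categorical factor
    model = smf.ols("overall_frequency ~ C(fraction) * C(family)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            "C(fraction)": "fraction",
            "C(family)": "family",
            "C(fraction):C(family)": "interaction",
            "Residual": "residual",
        }
    )
    aov["significant"] = aov["PR(>F)"] < alpha
    return aov


# ---- figures -----------------------------------------------------------


def plot_raster(result: SimResult, ax=None, title: str = ""):
    """Raster in the style of the network figures: GC band below, BC/MC/HC
    bands above, newborn GCs coloured."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    colors = {"mature": "k", "young_control": "tab:blue", "young_pilo": "tab:red",
              "BC": "tab:green", "MC": "tab:orange", "HC": "tab:purple"}
    for ci, s in enumerate(result.spikes):
        if not len(s):
            continue
        key = (result.populations[ci] or "mature") if result.cell_types[ci] == "GC" \
            else result.cell_types[ci]
        ax.plot(s, np.full(len(s), ci), "|", ms=3, color=colors.get(key, "gray"))
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("cell index")
    if title:
        ax.set_title(title)
    return ax


def plot_frequency_curves(summary: pd.DataFrame, ax=None):
    """Mean overall frequency vs newborn fraction per family, with SE bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for fam, g in summary.groupby("family"):
        stats = (
            g.dropna(subset=["overall_frequency"])
            .groupby("fraction")["overall_frequency"]
            .agg(["mean", "sem"])
            .reset_index()
        )
        ax.errorbar(stats["fraction"], stats["mean"], yerr=stats["sem"],
                    marker="o", capsize=3, label=fam)
    ax.set_xlabel("fraction of newborn GCs")
    ax.set_ylabel("overall frequency (spikes/s)")
    ax.legend(fontsize=8)
    return ax
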