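"""Diagnostic plots: Q-Q with cutoff, histogram + lateral boxplot, CDF,
per-image boxplots, and accuracy heatmaps for grid sweeps.

All functions draw onto a matplotlib Axes and return it; they are optional
artifacts — no computation depends on them.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless batch use; callers may switch backends first
import matplotlib.pyplot as plt

from .splitters import SplitResult, qq_points

__all__ = [
    "plot_qq",
    "plot_histogram",
    "plot_cdf",
    "plot_image_boxplots",
    "plot_accuracy_heatmap",
]


def plot_qq(values, result: Optional[SplitResult] = None, region=None, ax=None):
    """Normal Q-Q plot, optionally with regression line, region shading and cutoff."""
    if hasattr(values, "agv_values"):
        values = values.agv_values()
    ax = ax or plt.gca()
    qq = qq_points(values)
    ax.plot(qq.theor_quantiles, qq.sorted_values, ".", ms=2, color="0.3")
    if region is not None:
        ax.axhspan(region.lo, region.hi, color="orange", alpha=0.2, label="regression region")
    if result is not None:
        if result.slope is not None and result.median_large is not None:
            xs = np.array([qq.theor_quantiles[0], qq.theor_quantiles[-1]])
            ax.plot(xs, result.median_large + result.slope * xs, color="orange", lw=1.5,
                    label=f"slope (SD) = {result.slope:.2f}")
        ax.axhline(result.cutoff, color="red", ls="--",
                   label=f"cutoff = {result.cutoff:.1f} ({result.small_pct:.2f}% above)")
        ax.legend(loc="upper left", fontsize=8)
    ax.set_xlabel("theoretical normal quantile")
    ax.set_ylabel("AGV")
    return ax


def plot_histogram(values, result: Optional[SplitResult] = None, bins=60, ax=None):
    """Histogram with a lateral boxplot strip below, cutoff marked if given."""
    if hasattr(values, "agv_values"):
        values = values.agv_values()
    values = np.asarray(values, dtype=float)
    ax = ax or plt.gca()
    ax.hist(values, bins=bins, color="0.6", edgecolor="0.3")
    box_y = -0.06 * ax.get_ylim()[1]
    ax.boxplot(values, orientation="horizontal", positions=[box_y],
               widths=[-box_y * 0.8], manage_ticks=False, flierprops={"ms": 2})
    if result is not None:
        ax.axvline(result.cutoff, color="red", ls="--",
                   label=f"cutoff ({result.small_pct:.2f}% above)")
        ax.legend(fontsize=8)
    ax.set_xlabel("AGV")
    ax.set_ylabel("cells")
    return ax


def plot_cdf(values, result: Optional[SplitResult] = None, ax=None):
    """Empirical cumulative distribution of AGVs."""
    if hasattr(values, "agv_values"):
        values = values.agv_values()
    srt = np.sort(np.asarray(values, dtype=float))
    ax = ax or plt.gca()
    ax.step(srt, np.arange(1, srt.size + 1) / srt.size, where="post", color="0.3")
    if result is not None:
        ax.axvline(result.cutoff, color="red", ls="--")
    ax.set_xlabel("AGV")
    ax.set_ylabel("cumulative fraction")
    return ax


def plot_image_boxplots(dataset, summaries: Optional[Sequence] = None, ax=None):
    """Per-image boxplots for spotting acquisition bias; flagged images in red."""
    ax = ax or plt.gca()
    groups = dataset.by_image()
    labels = list(groups)
    ax.boxplot([groups[k] for k in labels], tick_labels=labels, flierprops={"ms": 2})
    if summaries is not None:
        flagged = {s.image_id for s in summaries if s.flagged}
        for tick in ax.get_xticklabels():
            if tick.get_text() in flagged:
                tick.set_color("red")
    ax.set_xlabel("image")
    ax.set_ylabel("AGV")
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_accuracy_heatmap(
    grid_df, x: str = "small_pct_true", y: str = "small_sd",
    fixed: Optional[dict] = None, vlim: float = 100.0, ax=None,
):
    """2-D accuracy heatmap from a long-format grid result.

    ``fixed`` selects a slice (e.g. ``{"small_mean": 130.8}``) when the grid
    sweeps three parameters; nearest grid value is used for each key.
    """
    df = grid_df
    if fixed:
        for key, val in fixed.items():
            levels = np.asarray(sorted(df[key].unique()))
            nearest = levels[np.argmin(np.abs(levels - val))]
            df = df[df[key] == nearest]
    pivot = df.pivot_table(index=y, columns=x, values="accuracy_pct")
    ax = ax or plt.gca()
    im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values,
                       cmap="RdBu_r", vmin=-vlim, vmax=vlim, shading="nearest")
    plt.colorbar(im, ax=ax, label="accuracy (%)")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    return ax
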