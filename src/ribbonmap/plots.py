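"""Figure helpers: histogram + fit overlays, normalized-curve comparison,
and box plots with the study's depiction contract (Q1-Q3 box, 5%/95%
whiskers, thick mean line, thin median line, diamonds beyond the
whiskers)."""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .profile import DrelHistogram, LogisticFit, eval_logistic
from .stats import GroupComparisonResult

__all__ = ["plot_histogram_fit", "plot_normalized_curves", "plot_group_boxes"]

log = logging.getLogger(__name__)

FIT_GRID_POINTS = 400


def plot_histogram_fit(hist: DrelHistogram, fit: LogisticFit | None = None,
                       ax=None, color="tab:blue"):
    """Bar histogram of d_rel with the fitted logistic curve overlaid and a
    dotted line at d_rel = 1 separating on-ribbon from off-ribbon values."""
    if ax is None:
        _, ax = plt.subplots()
    width = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.counts, width=width, align="edge",
           color=color, alpha=0.6, label=hist.label)
    if fit is not None:
        grid = np.linspace(hist.bin_edges[0], hist.bin_edges[-1],
                           FIT_GRID_POINTS)
        ax.plot(grid, eval_logistic(fit, grid), color="tab:orange", lw=2,
                label="logistic fit")
    ax.axvline(1.0, ls=":", color="k", lw=1)
    ax.set_xlabel(r"$d_{rel}$")
    ax.set_ylabel("gold particles")
    if hist.overflow:
        ax.set_title(f"overflow beyond range: {hist.overflow}")
    if ax.get_legend_handles_labels()[1]:
        ax.legend()
    return ax


def plot_normalized_curves(normalized_fits: dict, ax=None,
                           interval=(0.0, 13.0)):
    """Midline-normalized curves (f(0) = 100%) for each group on one axis."""
    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(*interval, FIT_GRID_POINTS)
    for g, fit in normalized_fits.items():
        ax.plot(grid, eval_logistic(fit, grid), lw=2, label=str(g))
    ax.axvline(1.0, ls=":", color="k", lw=1)
    ax.set_xlabel(r"$d_{rel}$")
    ax.set_ylabel("% of midline value")
    if normalized_fits:
        ax.legend()
    return ax


def plot_group_boxes(cmp_res: GroupComparisonResult, ax=None,
                     box_width: float = 0.6):
    """Box plot per group: Q1-Q3 box, whiskers at the 5% and 95% quantiles,
    thick mean and thin median lines, diamonds for points beyond the
    whiskers."""
    if ax is None:
        _, ax = plt.subplots()
    for i, g in enumerate(cmp_res.groups):
        b = cmp_res.box[g]
        x0, x1 = i - box_width / 2, i + box_width / 2
        if b["q1"] == b["q3"]:
            log.warning("group %s: degenerate box (Q1 == Q3)", g)
        ax.add_patch(plt.Rectangle((x0, b["q1"]), box_width,
                                   b["q3"] - b["q1"], fill=False, ec="k"))
        for y in (b["q05"], b["q95"]):
            ax.plot([i, i], [b["q1" if y < b["q1"] else "q3"], y], "k-", lw=1)
            ax.plot([i - box_width / 4, i + box_width / 4], [y, y], "k-", lw=1)
        ax.plot([x0, x1], [b["mean"], b["mean"]], "k-", lw=2.5)
        ax.plot([x0, x1], [b["median"], b["median"]], "k-", lw=1)
        for y in b["low_outliers"] + b["high_outliers"]:
            ax.plot(i, y, "kD", ms=4, fillstyle="none")
    ax.set_xticks(range(len(cmp_res.groups)))
    ax.set_xticklabels([str(g) for g in cmp_res.groups], rotation=30,
                       ha="right")
    ax.set_xlim(-0.8, len(cmp_res.groups) - 0.2)
    ax.relim(), ax.autoscale_view()
    return ax
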