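"""Model/results interface tying the pipeline together.

`RibbonTopographyModel` is built from annotations (or a precomputed
records table); `fit()` runs the full analysis — relative distances,
per-group d_rel histograms, logistic profile fits, midline-normalized
curves, inside/outside replicate summaries and nonparametric group
comparisons — and returns a `RibbonTopographyResults` carrying all of it,
with a `summary()` table and plotting helpers.

Typical use::

    model = RibbonTopographyModel.from_annotations(annotations)
    res = model.fit()
    print(res.summary())
    res.fits["6F4"].center, res.fits["6F4"].p
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import records_to_frame
from .profile import (DEFAULT_BIN_WIDTH, DEFAULT_RANGE, DrelHistogram,
                      LogisticFit, build_histogram, curve_separation,
                      eval_logistic, fit_logistic)
from .stats import (GroupComparisonResult, compare_groups,
                    compute_relative_distances, summarize_inside_outside)

__all__ = ["RibbonTopographyModel", "RibbonTopographyResults"]

log = logging.getLogger(__name__)


class RibbonTopographyModel:
    """Radial-topography analysis of labelled particles on ribbons.

    Parameters
    ----------
    records : DataFrame
        Tidy per-particle table with columns antibody, mouse, grid, ribbon,
        d1, d2, inside, degenerate, d_rel (as produced by
        :func:`ribbonmap.stats.compute_relative_distances`).
    bin_width, drel_range
        Histogram binning of d_rel (defaults 0.1 over [0, 13]).
    group_col, replicate_col
        Grouping label (default antibody) and statistical replicate unit
        (default grid).
    per_replicate_fit
        Also fit the logistic profile per replicate (for spread estimates)
        rather than only to the pooled per-group histogram.
    """

    def __init__(self, records: pd.DataFrame, *,
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 drel_range: tuple = DEFAULT_RANGE,
                 group_col: str = "antibody",
                 replicate_col: str = "grid",
                 per_replicate_fit: bool = False):
        required = {"d_rel", "degenerate", group_col, replicate_col, "ribbon"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"records table lacks columns: {sorted(missing)}")
        self.records = records.reset_index(drop=True)
        self.bin_width = bin_width
        self.drel_range = tuple(drel_range)
        self.group_col = group_col
        self.replicate_col = replicate_col
        self.per_replicate_fit = per_replicate_fit

    @classmethod
    def from_annotations(cls, annotations, *, trust_annotation_class=False,
                         **kwargs) -> "RibbonTopographyModel":
        records = compute_relative_distances(
            annotations, trust_annotation_class=trust_annotation_class)
        return cls(records_to_frame(records), **kwargs)

    @classmethod
    def from_records(cls, records, **kwargs) -> "RibbonTopographyModel":
        if not hasattr(records, "columns"):
            records = records_to_frame(records)
        return cls(records, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "RibbonTopographyResults":
        df = self.records
        n_degenerate = int(df["degenerate"].sum())
        usable = df[~df["degenerate"]]
        groups = list(pd.unique(usable[self.group_col].dropna())) or [None]

        histograms: dict = {}
        fits: dict = {}
        normalized_fits: dict = {}
        replicate_fits: dict = {}
        for g in groups:
            sub = usable if g is None else usable[usable[self.group_col] == g]
            hist = build_histogram(sub, self.bin_width, self.drel_range,
                                   label=str(g))
            histograms[g] = hist
            try:
                fits[g] = fit_logistic(hist)
                normalized_fits[g] = fits[g].normalized()
            except ValueError as e:
                log.warning("group %s: logistic fit unavailable (%s)", g, e)
                fits[g] = None
                normalized_fits[g] = None
            if self.per_replicate_fit:
                for rep, rsub in sub.groupby(self.replicate_col):
                    try:
                        replicate_fits[(g, rep)] = fit_logistic(
                            build_histogram(rsub, self.bin_width,
                                            self.drel_range, label=str(rep)))
                    except ValueError as e:
                        log.warning("replicate %s/%s not fitted: %s", g, rep, e)

        summary_table = summarize_inside_outside(
            usable, group_cols=(self.group_col,),
            replicate_col=self.replicate_col)

        comparison_counts = comparison_percent = None
        if len(groups) >= 2 and groups[0] is not None:
            counts, percents = {}, {}
            for g in groups:
                sub = summary_table[summary_table[self.group_col] == g]
                counts[(g, "inside")] = sub["per_ribbon_inside"].to_numpy()
                counts[(g, "outside")] = sub["per_ribbon_outside"].to_numpy()
                percents[(g, "inside")] = sub["percent_inside"].to_numpy()
                percents[(g, "outside")] = sub["percent_outside"].to_numpy()
            try:
                comparison_counts = compare_groups(counts)
                comparison_percent = compare_groups(percents)
            except ValueError as e:
                log.warning("group comparison skipped: %s", e)

        separation = None
        if len(groups) == 2 and all(f is not None and f.identifiable
                                    for f in fits.values()):
            separation = curve_separation(fits[groups[0]], fits[groups[1]])

        return RibbonTopographyResults(
            model=self, groups=groups, histograms=histograms, fits=fits,
            normalized_fits=normalized_fits, replicate_fits=replicate_fits,
            summary_table=summary_table,
            comparison_counts=comparison_counts,
            comparison_percent=comparison_percent,
            normalized_curve_separation=separation,
            n_degenerate=n_degenerate,
        )


@dataclass
class RibbonTopographyResults:
    """Fitted radial-topography analysis.

    Attributes
    ----------
    fits, normalized_fits : dict
        Per-group :class:`LogisticFit` of the pooled d_rel histogram, raw
        and midline-normalized (f(0) = 100%).
    summary_table : DataFrame
        Per-replicate inside/outside particle bookkeeping.
    comparison_counts, comparison_percent : GroupComparisonResult or None
        Kruskal-Wallis + Dunn's tests across group x location cells, on
        particles-per-ribbon and on percentages respectively.
    normalized_curve_separation : float or None
        Sup-norm difference of the two normalized curves on [0, 1] when
        exactly two groups are present.
    """

    model: RibbonTopographyModel
    groups: list
    histograms: dict
    fits: dict[object, LogisticFit]
    normalized_fits: dict[object, LogisticFit]
    replicate_fits: dict
    summary_table: pd.DataFrame
    comparison_counts: GroupComparisonResult | None
    comparison_percent: GroupComparisonResult | None
    normalized_curve_separation: float | None
    n_degenerate: int

    # -- tables -----------------------------------------------------------

    def fit_table(self) -> pd.DataFrame:
        rows = []
        for g, f in self.fits.items():
            if f is None:
                continue
            rows.append({"group": g, "a1": f.a1, "a2": f.a2,
                         "d_rel_center": f.center, "p": f.p, "rss": f.rss,
                         "converged": f.converged,
                         "identifiable": f.identifiable,
                         "n_particles": self.histograms[g].n})
        return pd.DataFrame(rows, columns=[
            "group", "a1", "a2", "d_rel_center", "p", "rss", "converged",
            "identifiable", "n_particles"])

    def percent_inside(self) -> pd.Series:
        """Mean percent of particles on the ribbon (d_rel <= 1) per group."""
        return self.summary_table.groupby(self.model.group_col)[
            "percent_inside"].mean()

    def summary(self) -> str:
        """Human-readable report of fits, summaries and comparisons."""
        from statsmodels.iolib.table import SimpleTable

        lines = ["Ribbon particle topography", "=" * 60]
        ft = self.fit_table()
        if len(ft):
            lines.append(SimpleTable(
            [[str(r["group"]), f"{r['a1']:.3f}", f"{r['a2']:.3f}",
              f"{r['d_rel_center']:.3f}", f"{r['p']:.3f}",
              str(int(r["n_particles"]))] for _, r in ft.iterrows()],
                headers=["group", "a1", "a2", "center", "p", "n"],
                title="Logistic radial profile, pooled fit").as_text())
        else:
            lines.append("logistic fit unavailable (too few informative "
                         "histogram bins)")
        pct = self.percent_inside()
        lines.append(SimpleTable(
            [[str(g), f"{v:.1f}"] for g, v in pct.items()],
            headers=["group", "% particles on ribbon (mean over replicates)"],
        ).as_text())
        if self.normalized_curve_separation is not None:
            lines.append("max |normalized curve difference| on [0, 1]: "
                         f"{self.normalized_curve_separation:.3f} "
                         "(percent of midline value)")
        for name, cmp_res in (("particles per ribbon", self.comparison_counts),
                              ("percent of particles", self.comparison_percent)):
            if cmp_res is not None:
                lines.append(
                    f"Kruskal-Wallis on {name}: H = {cmp_res.h_statistic:.3f}, "
                    f"p = {cmp_res.p_value:.4g}; Dunn's post hoc "
                    f"({cmp_res.adjustment})")
        if self.n_degenerate:
            lines.append(f"excluded degenerate records: {self.n_degenerate}")
        return "\n".join(lines)

    # -- curves & plots ---------------------------------------------------

    def curve(self, group, x, normalized: bool = False):
        fit = (self.normalized_fits if normalized else self.fits)[group]
        return eval_logistic(fit, x)

    def plot_histogram(self, group=None, ax=None, show_fit: bool = True):
        from .plots import plot_histogram_fit
        group = self.groups[0] if group is None else group
        return plot_histogram_fit(self.histograms[group],
                                  self.fits[group] if show_fit else None,
                                  ax=ax)

    def plot_normalized(self, ax=None, interval=(0.0, 13.0)):
        from .plots import plot_normalized_curves
        available = {g: f for g, f in self.normalized_fits.items()
                     if f is not None}
        return plot_normalized_curves(available, ax=ax, interval=interval)

    def plot_boxes(self, which: str = "percent", ax=None):
        from .plots import plot_group_boxes
        cmp_res = (self.comparison_percent if which == "percent"
                   else self.comparison_counts)
        if cmp_res is None:
            raise ValueError("no group comparison available")
        return plot_group_boxes(cmp_res, ax=ax)
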