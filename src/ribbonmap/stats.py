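"""Per-particle records to group statistics.

Turns annotations into relative-distance records, summarizes particle
counts inside (d_rel <= 1) versus outside (d_rel > 1) the ribbon per
replicate, and compares groups nonparametrically: a Kruskal-Wallis test on
replicate-level values followed by Dunn's post hoc pairwise z tests with
Bonferroni adjustment (p multiplied by the number of pairwise comparisons,
capped at 1).  The statistical replicate is the immunolabelled grid.

Dunn's test is computed directly: with pooled ranks R of all N replicate
values and mean rank Ri per group,

    z_ij = (Ri - Rj) / sqrt((N(N+1)/12 - C) (1/ni + 1/nj)),

where C = sum(t^3 - t) / (12 (N - 1)) corrects for ties of multiplicity t.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations import RibbonAnnotation, records_to_frame
from .geometry import InvalidAnnotationError, relative_distance

__all__ = [
    "compute_relative_distances",
    "summarize_inside_outside",
    "box_stats",
    "dunn_test",
    "compare_groups",
    "GroupComparisonResult",
]

log = logging.getLogger(__name__)


def compute_relative_distances(annotations, *, trust_annotation_class=False):
    """One relative-distance record per particle across annotations.

    Containment is recomputed from the outline by default; disagreements
    with the manual inside/outside class are logged.  With
    ``trust_annotation_class=True`` the manual class routes the inside vs
    outside formula instead.  Annotations failing geometric preconditions
    (midline escaping the outline, midline touching the border at a
    particle) are skipped with a logged error and the run continues.
    """
    records = []
    for idx, ann in enumerate(annotations):
        if not ann.outline.polygon.buffer(1e-9).covers(ann.midpoints.line):
            log.error("annotation %s: midline not inside outline; skipped",
                      ann.provenance.get("ribbon", idx))
            continue
        try:
            for x, y, cls in ann.particles:
                manual = {"inside": True, "outside": False}.get(cls)
                rec = relative_distance(
                    (x, y), ann.midpoints, ann.outline,
                    inside=manual if (trust_annotation_class and manual is not None)
                    else None,
                    provenance=ann.provenance,
                )
                if manual is not None and rec.inside != manual \
                        and not trust_annotation_class:
                    log.warning(
                        "annotation %s: particle (%g, %g) recomputed as %s but "
                        "marked %s", ann.provenance.get("ribbon", idx), x, y,
                        "inside" if rec.inside else "outside", cls)
                if rec.degenerate:
                    log.warning(
                        "annotation %s: degenerate outside particle (%g, %g) "
                        "excluded (d1 - d2 ~ 0)",
                        ann.provenance.get("ribbon", idx), x, y)
                records.append(rec)
        except InvalidAnnotationError as e:
            log.error("annotation %s: %s; skipped",
                      ann.provenance.get("ribbon", idx), e)
    return records


def summarize_inside_outside(records, group_cols=("antibody",),
                             replicate_col="grid") -> pd.DataFrame:
    """Per-replicate particle bookkeeping: particles-per-ribbon inside and
    outside the ribbon, and the percentage of all particles in each class.

    ``inside`` here means d_rel <= 1 (on the ribbon), the interval the
    inside formula produces.  Degenerate records are excluded with a logged
    count.  Ribbons are counted from the ribbon ids present in the records.
    """
    df = records_to_frame(records) if not hasattr(records, "columns") else records
    n_deg = int(df["degenerate"].sum())
    if n_deg:
        log.info("excluding %d degenerate records from summary", n_deg)
    df = df[~df["degenerate"]]
    if df.empty:
        raise ValueError("no usable records to summarize")
    group_cols = list(group_cols)
    rows = []
    for keys, sub in df.groupby(group_cols + [replicate_col], dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n_ribbons = sub["ribbon"].nunique()
        if n_ribbons == 0:
            raise ValueError(f"replicate {keys} has zero ribbons")
        n_in = int((sub["d_rel"] <= 1.0).sum())
        n_out = int((sub["d_rel"] > 1.0).sum())
        n = n_in + n_out
        rows.append(dict(zip(group_cols, keys[:-1]))
                    | {replicate_col: keys[-1],
                       "n_ribbons": n_ribbons,
                       "n_inside": n_in, "n_outside": n_out,
                       "per_ribbon_inside": n_in / n_ribbons,
                       "per_ribbon_outside": n_out / n_ribbons,
                       "percent_inside": 100.0 * n_in / n,
                       "percent_outside": 100.0 * n_out / n})
    return pd.DataFrame(rows)


def box_stats(values) -> dict:
    """Box-plot statistics: Q1-Q3 box, 5%/95% whiskers, mean and median.

    Quantiles use linear interpolation of the empirical CDF (numpy's
    default, type 7).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    q05, q25, q50, q75, q95 = np.quantile(v, [0.05, 0.25, 0.5, 0.75, 0.95])
    return {"q05": q05, "q1": q25, "median": q50, "q3": q75, "q95": q95,
            "mean": float(v.mean()),
            "low_outliers": v[v < q05].tolist(),
            "high_outliers": v[v > q95].tolist()}


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis global test plus Dunn's pairwise post hoc results."""

    groups: list
    n_per_group: dict
    h_statistic: float
    p_value: float
    z: pd.DataFrame
    p_unadjusted: pd.DataFrame
    p_adjusted: pd.DataFrame
    adjustment: str = "bonferroni"
    box: dict = field(default_factory=dict)

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple]:
        out = []
        for a, b in itertools.combinations(self.groups, 2):
            if self.p_adjusted.at[a, b] <= alpha:
                out.append((a, b))
        return out


def dunn_test(samples: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn's pairwise z statistics and two-sided p-values (unadjusted).

    Returns (z, p) as symmetric DataFrames indexed by group label.
    """
    groups = list(samples)
    values = np.concatenate([np.asarray(samples[g], dtype=float) for g in groups])
    sizes = np.array([len(samples[g]) for g in groups])
    n_total = values.size
    ranks = sps.rankdata(values)
    mean_ranks = {}
    start = 0
    for g, sz in zip(groups, sizes):
        mean_ranks[g] = ranks[start:start + sz].mean()
        start += sz
    _, tie_counts = np.unique(values, return_counts=True)
    tie_corr = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    # tuple labels (e.g. antibody x location) stay scalar keys, not levels
    idx = pd.Index(groups, tupleize_cols=False)
    z = pd.DataFrame(0.0, index=idx, columns=idx)
    p = pd.DataFrame(1.0, index=idx, columns=idx)
    for (i, a), (j, b) in itertools.combinations(enumerate(groups), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        zij = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pij = 2.0 * sps.norm.sf(abs(zij))
        z.at[a, b], z.at[b, a] = zij, -zij
        p.at[a, b] = p.at[b, a] = pij
    return z, p


def compare_groups(samples: dict) -> GroupComparisonResult:
    """Kruskal-Wallis across groups of replicate-level values, then Dunn's
    post hoc pairwise comparisons with Bonferroni adjustment.

    Parameters
    ----------
    samples : dict
        Mapping group label -> 1-D array of replicate values (>= 2 groups,
        >= 2 replicates each).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in samples.items():
        if len(np.atleast_1d(v)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    arrays = [np.asarray(v, dtype=float) for v in samples.values()]
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # identical samples: no evidence of any difference
        h, p_global = 0.0, 1.0
    else:
        try:
            h, p_global = sps.kruskal(*arrays)
        except ValueError:  # all values identical across groups
            h, p_global = 0.0, 1.0
    z, p_unadj = dunn_test(samples)
    m = len(samples) * (len(samples) - 1) // 2
    p_adj = (p_unadj * m).clip(upper=1.0)
    np.fill_diagonal(p_adj.values, 1.0)
    return GroupComparisonResult(
        groups=list(samples),
        n_per_group={g: len(np.atleast_1d(v)) for g, v in samples.items()},
        h_statistic=float(h), p_value=float(p_global),
        z=z, p_unadjusted=p_unadj, p_adjusted=p_adj,
        adjustment=f"bonferroni (x{m}, capped at 1)",
        box={g: box_stats(v) for g, v in samples.items()},
    )
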