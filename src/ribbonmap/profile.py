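"""Radial labelling profile: d_rel histograms and the four-parameter
logistic curve.

The frequency distribution of relative distances is summarized by a
histogram over [0, 13] and fitted with the four-parameter logistic

    f(d_rel) = a2 + (a1 - a2) / (1 + (d_rel / c)^p)

where ``a1 = f(0)`` is the count at the ribbon midline, ``a2`` the asymptote
as d_rel grows without bound, ``c`` the half-decay point (``f(c) =
(a1 + a2)/2``) and ``p`` the power controlling the steepness of the decay.
To compare antibodies of different labelling intensity, curves are
normalized so that the midline value f(0) is 100%; the normalization only
rescales a1 and a2 and preserves the logistic shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DrelHistogram",
    "LogisticFit",
    "UnderdeterminedFitError",
    "build_histogram",
    "logistic",
    "fit_logistic",
    "eval_logistic",
    "normalize_to_midline",
    "curve_separation",
]

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_RANGE = (0.0, 13.0)


class UnderdeterminedFitError(ValueError):
    """Too few informative histogram bins to constrain four parameters."""


@dataclass(frozen=True)
class DrelHistogram:
    """Binned d_rel counts: right-open bins, last bin closed, plus an
    overflow tally for values beyond the range."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow: int = 0
    label: str | None = None

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum()) + self.overflow


def _extract_drel(records) -> np.ndarray:
    """Accept an array of d_rel values, a records table, or record objects."""
    if hasattr(records, "columns"):  # DataFrame
        df = records
        if "degenerate" in df.columns:
            df = df[~df["degenerate"]]
        return df["d_rel"].to_numpy(dtype=float)
    records = list(records) if not isinstance(records, np.ndarray) else records
    if len(records) and hasattr(records[0], "d_rel"):
        return np.array([r.d_rel for r in records if not r.degenerate], dtype=float)
    return np.asarray(records, dtype=float)


def build_histogram(records, bin_width: float = DEFAULT_BIN_WIDTH,
                    drel_range: tuple[float, float] = DEFAULT_RANGE,
                    label: str | None = None) -> DrelHistogram:
    """Bin relative distances at the given width over ``drel_range``.

    Bins are right-open [e_i, e_{i+1}) except the last, which is closed;
    values above the range are counted in ``overflow`` and reported
    separately.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = drel_range
    if hi <= lo:
        raise ValueError("drel_range must be increasing")
    values = _extract_drel(records)
    values = values[np.isfinite(values)]
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    in_range = values <= edges[-1]
    counts, _ = np.histogram(values[in_range], bins=edges)
    overflow = int((~in_range).sum())
    return DrelHistogram(bin_edges=edges, counts=counts.astype(int),
                         overflow=overflow, label=label)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted four-parameter logistic profile with diagnostics.

    ``identifiable`` is False when the data cannot constrain the shape
    (flat histogram: a1 == a2, so center and p are arbitrary).
    """

    a1: float
    a2: float
    center: float
    p: float
    rss: float = np.nan
    converged: bool = True
    identifiable: bool = True
    param_se: tuple | None = None
    label: str | None = None

    def __call__(self, x):
        return eval_logistic(self, x)

    def normalized(self) -> "LogisticFit":
        return normalize_to_midline(self)


def logistic(x, a1: float, a2: float, center: float, p: float):
    """f(x) = a2 + (a1 - a2) / (1 + (x / center)^p); f(0) = a1 exactly."""
    x = np.asarray(x, dtype=float)
    vals = a2 + (a1 - a2) / (1.0 + np.power(x / center, p))
    # enforce the algebraic identity f(0) = a1 against float round-off
    return np.where(x == 0.0, a1, vals)


def fit_logistic(hist: DrelHistogram, *, xtol: float = 1e-8,
                 label: str | None = None) -> LogisticFit:
    """Least-squares logistic fit to (bin-center, count) pairs.

    Initialization: a1 = max count, a2 = 0, center = 1, p = 3; the center
    and power are bounded positive.  Non-convergence is reported through the
    ``converged`` flag, never silently.
    """
    x = hist.centers
    y = hist.counts.astype(float)
    if int((y > 0).sum()) < 5:
        raise UnderdeterminedFitError(
            f"only {(y > 0).sum()} non-empty bins; need at least 5 to "
            "constrain four parameters"
        )
    label = label if label is not None else hist.label
    if np.ptp(y) == 0.0:
        c = float(y[0])
        log.warning("flat histogram: shape parameters unidentifiable")
        return LogisticFit(a1=c, a2=c, center=1.0, p=3.0, rss=0.0,
                           converged=True, identifiable=False, label=label)
    p0 = [float(y.max()), 0.0, 1.0, 3.0]
    tiny = np.finfo(float).tiny
    bounds = ([-np.inf, -np.inf, tiny, tiny], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(logistic, x, y, p0=p0, bounds=bounds,
                               xtol=xtol, ftol=xtol, maxfev=20000)
        converged = True
    except RuntimeError:
        log.warning("logistic fit did not converge")
        popt, pcov = p0, np.full((4, 4), np.nan)
        converged = False
    a1, a2, center, p = (float(v) for v in popt)
    rss = float(np.sum((y - logistic(x, *popt)) ** 2))
    with np.errstate(invalid="ignore"):
        se = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    identifiable = abs(a1 - a2) > 1e-6 * max(1.0, abs(a1))
    if not identifiable:
        log.warning("fitted curve is flat (a1 ~ a2): center and p unidentifiable")
    return LogisticFit(a1=a1, a2=a2, center=center, p=p, rss=rss,
                       converged=converged, identifiable=identifiable,
                       param_se=se, label=label)


def eval_logistic(fit: LogisticFit, x):
    """Evaluate the fitted curve at non-negative d_rel values."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("d_rel must be non-negative")
    out = logistic(x, fit.a1, fit.a2, fit.center, fit.p)
    return float(out) if out.ndim == 0 else out


def normalize_to_midline(obj):
    """Rescale so the midline value f(d_rel = 0) is 100%.

    For a :class:`LogisticFit` this scales a1 and a2 by 100/a1 (the logistic
    shape is preserved, so no refit is needed); for a :class:`DrelHistogram`
    the counts are divided by the first-bin count.  Idempotent.
    """
    if isinstance(obj, LogisticFit):
        if obj.a1 == 0:
            raise ValueError("cannot normalize: f(0) = a1 = 0")
        s = 100.0 / obj.a1
        se = None
        if obj.param_se is not None:
            se = (abs(s) * obj.param_se[0], abs(s) * obj.param_se[1],
                  obj.param_se[2], obj.param_se[3])
        return replace(obj, a1=100.0, a2=obj.a2 * s, rss=obj.rss * s * s,
                       param_se=se)
    if isinstance(obj, DrelHistogram):
        f0 = float(obj.counts[0])
        if f0 == 0:
            raise ValueError("cannot normalize: first-bin count is 0")
        return obj.bin_edges, obj.counts * (100.0 / f0)
    raise TypeError("expected LogisticFit or DrelHistogram")


def curve_separation(fit_a: LogisticFit, fit_b: LogisticFit,
                     interval: tuple[float, float] = (0.0, 1.0),
                     n_points: int = 201, normalize: bool = True) -> float:
    """Maximum absolute difference between two (normalized) curves on an
    interval — the scale on which two antibodies' radial profiles are
    compared after midline normalization."""
    if normalize:
        fit_a, fit_b = fit_a.normalized(), fit_b.normalized()
    grid = np.linspace(*interval, n_points)
    return float(np.max(np.abs(eval_logistic(fit_a, grid)
                               - eval_logistic(fit_b, grid))))
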