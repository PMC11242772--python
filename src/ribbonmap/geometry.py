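"""Planar geometry for ribbon cross-sections: midline/border distances and
the normalized relative distance.

A ribbon cross-section in a transmission-EM image is annotated by a closed
outer-border polygon and an open midline polyline.  For a gold particle at
point ``p`` the two primitive measurements are

* ``d1`` — minimal Euclidean distance from ``p`` to the midline polyline,
* ``d2`` — minimal Euclidean distance from ``p`` to the outer border.

The normalized relative distance is then

* inside the border:  ``d_rel = d1 / (d1 + d2)``   (0 on the midline,
  1 on the border),
* outside the border: ``d_rel = d1 / (d1 - d2)``   (> 1, growing with
  distance from the ribbon surface).

Both forms divide out the local half-width of the ribbon, so ``d_rel`` is
invariant under rigid motion and uniform scaling of the image — the apparent
width of a sectioned ribbon depends on the section angle, and the
normalization corrects for it.

Coordinates are 0-based image pixel coordinates (origin top-left, y down);
because every output is dimensionless the convention never leaks into
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "InvalidAnnotationError",
    "Midline",
    "RibbonOutline",
    "RelativeDistanceRecord",
    "min_distance_to_polyline",
    "point_in_outline",
    "relative_distance",
]

#: relative guard on the Eq.-(2) denominator ``d1 - d2``
DEGENERATE_EPS = 1e-9


class InvalidAnnotationError(ValueError):
    """Raised when an annotation violates its geometric invariants."""


def _as_points(points: Sequence, min_points: int, name: str) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidAnnotationError(f"{name} must be an (N, 2) array of xy points")
    if arr.shape[0] < min_points:
        raise InvalidAnnotationError(
            f"{name} needs at least {min_points} points, got {arr.shape[0]}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidAnnotationError(f"{name} contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class Midline:
    """Open polyline through the ribbon center, from ordered midpoints."""

    points: np.ndarray

    def __init__(self, points: Sequence):
        arr = _as_points(points, 2, "midline")
        seg = np.diff(arr, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise InvalidAnnotationError("midline has zero-length segments")
        object.__setattr__(self, "points", arr)

    @property
    def line(self) -> LineString:
        return LineString(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RibbonOutline:
    """Simple closed polygon demarcating the outer border of the ribbon.

    Vertices are stored open (last edge back to the first is implicit).
    """

    vertices: np.ndarray

    def __init__(self, vertices: Sequence):
        arr = _as_points(vertices, 3, "outline")
        if np.array_equal(arr[0], arr[-1]):
            arr = arr[:-1]
        if arr.shape[0] < 3:
            raise InvalidAnnotationError("outline needs at least 3 distinct vertices")
        poly = Polygon(arr)
        if not poly.is_valid:
            raise InvalidAnnotationError("outline polygon is self-intersecting")
        if poly.area <= 0:
            raise InvalidAnnotationError("outline polygon has zero area")
        object.__setattr__(self, "vertices", arr)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def boundary(self) -> LineString:
        return self.polygon.exterior

    @property
    def area(self) -> float:
        return self.polygon.area

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class RelativeDistanceRecord:
    """Per-particle measurement: d1, d2, inside flag and d_rel.

    ``degenerate`` marks outside particles whose Eq.-(2) denominator
    ``d1 - d2`` vanished within the epsilon guard; such records are excluded
    from downstream statistics.  ``provenance`` carries grouping labels
    (antibody, mouse, grid, ribbon) untouched.
    """

    particle: tuple[float, float]
    d1: float
    d2: float
    inside: bool
    d_rel: float
    degenerate: bool = False
    provenance: dict = field(default_factory=dict)


def min_distance_to_polyline(p, line) -> float:
    """Minimal Euclidean distance from point ``p`` to a polyline.

    ``line`` may be a :class:`Midline` (open) or a :class:`RibbonOutline`
    (its closed boundary, last->first edge included).  Exact point-to-segment
    distance, minimized over all segments.
    """
    if isinstance(line, Midline):
        geom = line.line
    elif isinstance(line, RibbonOutline):
        geom = line.boundary
    else:
        arr = _as_points(line, 2, "polyline")
        if np.all(arr == arr[0]):
            raise InvalidAnnotationError("degenerate polyline: all points identical")
        geom = LineString(arr)
    return float(Point(float(p[0]), float(p[1])).distance(geom))


def point_in_outline(p, outline: RibbonOutline) -> bool:
    """Even-odd containment; points exactly on the border count as inside.

    The boundary convention makes the inside/outside partition exhaustive
    and matches the inside-formula limit d_rel -> 1 as d2 -> 0.
    """
    return bool(outline.polygon.covers(Point(float(p[0]), float(p[1]))))


def relative_distance(
    p,
    midline: Midline,
    outline: RibbonOutline,
    *,
    inside: bool | None = None,
    provenance: dict | None = None,
) -> RelativeDistanceRecord:
    """Compute d1, d2 and the normalized relative distance of a particle.

    Parameters
    ----------
    p : (x, y)
        Particle position in pixels.
    midline, outline
        Ribbon annotation geometry; the midline must lie within the outline.
    inside : bool, optional
        Trusted manual inside/outside class.  By default containment is
        recomputed from the outline; pass the manual class to reproduce a
        workflow that routed the two formulas by manual color class.
    provenance : dict, optional
        Grouping labels copied onto the record.

    Returns
    -------
    RelativeDistanceRecord
    """
    x, y = float(p[0]), float(p[1])
    d1 = min_distance_to_polyline((x, y), midline)
    d2 = min_distance_to_polyline((x, y), outline)
    if inside is None:
        inside = point_in_outline((x, y), outline)

    degenerate = False
    if inside:
        denom = d1 + d2
        if denom == 0.0:
            raise InvalidAnnotationError(
                "midline touches the outline where the particle sits (d1 = d2 = 0)"
            )
        d_rel = d1 / denom
    else:
        denom = d1 - d2
        # geometrically d1 > d2 outside; guard near-degenerate annotations
        if denom <= DEGENERATE_EPS * d1:
            degenerate = True
            d_rel = np.nan
        else:
            d_rel = d1 / denom
    return RelativeDistanceRecord(
        particle=(x, y),
        d1=d1,
        d2=d2,
        inside=bool(inside),
        d_rel=d_rel,
        degenerate=degenerate,
        provenance=dict(provenance or {}),
    )


def batch_relative_distance(
    points: np.ndarray, midline: Midline, outline: RibbonOutline
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized d1/d2/inside/d_rel for an (N, 2) array of particles.

    Returns ``(d1, d2, inside, d_rel)`` arrays; degenerate outside particles
    get ``d_rel = nan``.  Used by the simulation's rejection sampler where
    per-point Python overhead would dominate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        z = np.empty(0)
        return z, z.copy(), np.empty(0, dtype=bool), z.copy()
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    d1 = shapely.distance(geoms, midline.line)
    poly = outline.polygon
    d2 = shapely.distance(geoms, poly.exterior)
    inside = shapely.covers(poly, geoms)
    d_rel = np.full(len(pts), np.nan)
    d_rel[inside] = d1[inside] / (d1[inside] + d2[inside])
    out = ~inside
    denom = d1[out] - d2[out]
    ok = denom > DEGENERATE_EPS * d1[out]
    vals = np.full(out.sum(), np.nan)
    vals[ok] = d1[out][ok] / denom[ok]
    d_rel[out] = vals
    return d1, d2, inside, d_rel
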