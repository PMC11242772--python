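"""Parse colored raster overlays into annotations.

Mirrors a manual marking workflow: on a copy of the micrograph the ribbon
border is traced as a closed curve in one color, midpoints and particles
are marked as small dots in dedicated colors (inside- and outside-particles
in two different colors).  Parsing recovers

* particle positions as centroids of connected components of each particle
  color,
* midpoints as centroids of midpoint-color components, ordered along the
  first principal axis of their point set (drawing order is not recoverable
  from a flat raster),
* the outline as the traced closed curve, filled, contour-followed and
  decimated to an ordered polygon (vertex tolerance 0.5 px).

Color matching is exact RGB by default, with an optional per-channel
tolerance for anti-aliased markings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure

from .annotations import RibbonAnnotation
from .geometry import Midline, RibbonOutline

__all__ = ["OverlayPalette", "OverlayParseError", "parse_overlay",
           "render_overlay"]

log = logging.getLogger(__name__)

OUTLINE_DECIMATION_TOL = 0.5


class OverlayParseError(ValueError):
    pass


@dataclass(frozen=True)
class OverlayPalette:
    """Exact RGB triples for the four marking colors."""

    outline_color: tuple[int, int, int] = (255, 0, 0)
    midpoint_color: tuple[int, int, int] = (255, 255, 0)
    inside_particle_color: tuple[int, int, int] = (0, 0, 255)
    outside_particle_color: tuple[int, int, int] = (0, 255, 0)

    def __post_init__(self):
        colors = [self.outline_color, self.midpoint_color,
                  self.inside_particle_color, self.outside_particle_color]
        if len({tuple(c) for c in colors}) != 4:
            raise ValueError("palette colors must be pairwise distinct")


def _load_rgb(image) -> np.ndarray:
    if isinstance(image, np.ndarray):
        if image.ndim != 3 or image.shape[2] < 3:
            raise OverlayParseError("expected an RGB raster (H, W, 3)")
        return image[..., :3]
    return np.asarray(Image.open(image).convert("RGB"))


def _color_mask(rgb: np.ndarray, color, tol: int) -> np.ndarray:
    diff = np.abs(rgb.astype(int) - np.asarray(color, dtype=int))
    return np.all(diff <= tol, axis=-1)


def _components(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroids (x, y) and pixel areas of connected components."""
    labels, n = measure.label(mask, return_num=True, connectivity=2)
    if n == 0:
        return np.empty((0, 2)), np.empty(0)
    props = measure.regionprops(labels)
    cents = np.array([[p.centroid[1], p.centroid[0]] for p in props])
    areas = np.array([p.area for p in props], dtype=float)
    return cents, areas


def _order_along_principal_axis(points: np.ndarray) -> np.ndarray:
    if len(points) < 3:
        return points
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    return points[order]


def parse_overlay(image, palette: OverlayPalette | None = None,
                  color_tolerance: int = 0) -> RibbonAnnotation:
    """Recover an annotation (without provenance) from a marked raster.

    ``image`` is a path to a PNG/TIFF or an (H, W, 3) uint8 array.
    """
    palette = palette or OverlayPalette()
    rgb = _load_rgb(image)

    outline_mask = _color_mask(rgb, palette.outline_color, color_tolerance)
    if not outline_mask.any():
        raise OverlayParseError("no outline-colored pixels in the image")
    filled = ndimage.binary_fill_holes(outline_mask)
    if filled.sum() <= outline_mask.sum():
        raise OverlayParseError("outline curve does not close around an area")
    contours = measure.find_contours(filled.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col)
    poly_rc = measure.approximate_polygon(contour, OUTLINE_DECIMATION_TOL)
    if np.array_equal(poly_rc[0], poly_rc[-1]):
        poly_rc = poly_rc[:-1]
    outline = RibbonOutline(poly_rc[:, ::-1])

    mid_pts, mid_areas = _components(
        _color_mask(rgb, palette.midpoint_color, color_tolerance))
    if len(mid_pts) < 2:
        raise OverlayParseError(
            f"found {len(mid_pts)} midpoint dots; need at least 2")
    midline = Midline(_order_along_principal_axis(mid_pts))

    particles = []
    all_areas = [mid_areas]
    per_color = []
    for color, cls in ((palette.inside_particle_color, "inside"),
                       (palette.outside_particle_color, "outside")):
        cents, areas = _components(_color_mask(rgb, color, color_tolerance))
        per_color.append((cls, cents, areas))
        all_areas.append(areas)
        particles.extend((float(x), float(y), cls) for x, y in cents)
    # a component much larger than the typical dot suggests merged dots
    ref = float(np.median(np.concatenate(all_areas)))
    for cls, cents, areas in per_color:
        for (x, y), a in zip(cents, areas):
            if a > 1.6 * ref:
                log.warning(
                    "%s-particle component at (%.1f, %.1f) covers %d px "
                    "(typical dot %d px); overlapping dots may have merged "
                    "into one", cls, x, y, int(a), int(ref))

    return RibbonAnnotation(outline=outline, midpoints=midline,
                            particles=particles)


def render_overlay(annotation: RibbonAnnotation, shape: tuple[int, int],
                   palette: OverlayPalette | None = None,
                   dot_radius: int = 2,
                   background: tuple[int, int, int] = (30, 30, 30)
                   ) -> np.ndarray:
    """Draw an annotation onto a blank RGB raster with the given palette.

    The inverse of :func:`parse_overlay` up to rasterization; used to
    validate the parser and to preview annotations.
    """
    palette = palette or OverlayPalette()
    h, w = shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = background

    verts = annotation.outline.vertices
    rows = np.round(verts[:, 1]).astype(int)
    cols = np.round(verts[:, 0]).astype(int)
    rr, cc = skdraw.polygon_perimeter(rows, cols, shape=(h, w), clip=True)
    img[rr, cc] = palette.outline_color

    def dot(x, y, color):
        rr, cc = skdraw.disk((y, x), dot_radius, shape=(h, w))
        img[rr, cc] = color

    for x, y in annotation.midpoints.points:
        dot(x, y, palette.midpoint_color)
    for x, y, cls in annotation.particles:
        color = (palette.inside_particle_color if cls == "inside"
                 else palette.outside_particle_color)
        dot(x, y, color)
    return img
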