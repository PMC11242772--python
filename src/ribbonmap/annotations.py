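"""Reading and writing ribbon annotations.

The native on-disk format is a small versioned JSON schema,
``ribbonmap-annotation/1`` — one object per ribbon, or a list of objects for
all ribbons of one image::

    {
      "schema": "ribbonmap-annotation/1",
      "nm_per_px": 1.2,                      # optional physical scale
      "provenance": {"antibody": "...", "mouse": "...", "embedding": "...",
                     "grid": "...", "ribbon": "...", "image": "..."},
      "outline":   [[x, y], ...],            # closed border polygon, >=3 pts
      "midpoints": [[x, y], ...],            # ordered midline points, >=2
      "particles": [{"x": .., "y": .., "class": "inside"}, ...]
    }

Geometry is serialized as decimal text via Python's shortest-round-trip
float repr, so write -> read is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import InvalidAnnotationError, Midline, RibbonOutline

__all__ = [
    "SCHEMA_VERSION",
    "PARTICLE_CLASSES",
    "AnnotationSchemaError",
    "RibbonAnnotation",
    "read_annotation",
    "read_annotations",
    "write_annotation",
    "write_annotations",
    "records_to_frame",
    "write_records_csv",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "ribbonmap-annotation/1"
PARTICLE_CLASSES = ("inside", "outside", "unclassified")
PROVENANCE_KEYS = ("antibody", "mouse", "embedding", "grid", "ribbon", "image")

#: sane range for the number of midline points (manual annotations use 5-20)
MIDPOINT_RANGE = (2, 50)


class AnnotationSchemaError(ValueError):
    """Schema violation, reported with the offending field path."""


@dataclass
class RibbonAnnotation:
    """One ribbon's geometry plus classified particle coordinates."""

    outline: RibbonOutline
    midpoints: Midline
    particles: list[tuple[float, float, str]] = field(default_factory=list)
    nm_per_px: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = MIDPOINT_RANGE
        n = len(self.midpoints)
        if not lo <= n <= hi:
            raise AnnotationSchemaError(
                f"midpoints: count {n} outside sane range [{lo}, {hi}]"
            )
        for i, p in enumerate(self.particles):
            if len(p) != 3 or p[2] not in PARTICLE_CLASSES:
                raise AnnotationSchemaError(
                    f"particles[{i}]: expected (x, y, class) with class in "
                    f"{PARTICLE_CLASSES}"
                )
        if self.nm_per_px is not None and not self.nm_per_px > 0:
            raise AnnotationSchemaError("nm_per_px: must be positive")

    @property
    def particle_xy(self) -> np.ndarray:
        if not self.particles:
            return np.empty((0, 2))
        return np.array([(p[0], p[1]) for p in self.particles], dtype=float)

    def to_dict(self) -> dict:
        d: dict = {"schema": SCHEMA_VERSION}
        if self.nm_per_px is not None:
            d["nm_per_px"] = float(self.nm_per_px)
        d["provenance"] = {k: self.provenance[k] for k in PROVENANCE_KEYS
                           if k in self.provenance}
        d["outline"] = [[float(x), float(y)] for x, y in self.outline.vertices]
        d["midpoints"] = [[float(x), float(y)] for x, y in self.midpoints.points]
        d["particles"] = [
            {"x": float(x), "y": float(y), "class": c} for x, y, c in self.particles
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict, path: str = "") -> "RibbonAnnotation":
        def err(fieldpath, msg):
            where = f"{path}:{fieldpath}" if path else fieldpath
            raise AnnotationSchemaError(f"{where}: {msg}")

        if not isinstance(d, dict):
            err("", "annotation must be a JSON object")
        if d.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
            err("schema", f"unsupported schema {d.get('schema')!r}")
        for key in ("outline", "midpoints"):
            if key not in d:
                err(key, "missing required field")
        try:
            outline = RibbonOutline(d["outline"])
        except (InvalidAnnotationError, TypeError, ValueError) as e:
            err("outline", str(e))
        try:
            midpoints = Midline(d["midpoints"])
        except (InvalidAnnotationError, TypeError, ValueError) as e:
            err("midpoints", str(e))
        particles = []
        for i, p in enumerate(d.get("particles", [])):
            try:
                particles.append(
                    (float(p["x"]), float(p["y"]), p.get("class", "unclassified"))
                )
            except (KeyError, TypeError, ValueError):
                err(f"particles[{i}]", "expected object with x, y, class")
            if particles[-1][2] not in PARTICLE_CLASSES:
                err(f"particles[{i}].class", f"must be one of {PARTICLE_CLASSES}")
        nm_per_px = d.get("nm_per_px")
        if nm_per_px is not None:
            nm_per_px = float(nm_per_px)
        try:
            return cls(
                outline=outline,
                midpoints=midpoints,
                particles=particles,
                nm_per_px=nm_per_px,
                provenance=dict(d.get("provenance", {})),
            )
        except AnnotationSchemaError as e:
            err("", str(e))


def read_annotation(path) -> RibbonAnnotation:
    """Read a single-ribbon annotation file."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        if len(data) != 1:
            raise AnnotationSchemaError(
                f"{path}: expected one annotation, found {len(data)}; "
                "use read_annotations for multi-ribbon files"
            )
        data = data[0]
    return RibbonAnnotation.from_dict(data, path=str(path))


def read_annotations(path) -> list[RibbonAnnotation]:
    """Read a file holding one annotation object or a list of them."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [RibbonAnnotation.from_dict(d, path=f"{path}[{i}]")
            for i, d in enumerate(data)]


def write_annotation(annotation: RibbonAnnotation, path) -> None:
    """Serialize one annotation as JSON (lossless, stable key order)."""
    Path(path).write_text(json.dumps(annotation.to_dict(), indent=1) + "\n")


def write_annotations(annotations, path) -> None:
    """Serialize a list of annotations (one JSON array)."""
    Path(path).write_text(
        json.dumps([a.to_dict() for a in annotations], indent=1) + "\n"
    )


_RECORD_COLUMNS = [
    "antibody", "mouse", "embedding", "grid", "ribbon",
    "x", "y", "d1", "d2", "inside", "degenerate", "d_rel",
]


def records_to_frame(records) -> pd.DataFrame:
    """Relative-distance records as a tidy table, one row per particle."""
    rows = []
    for r in records:
        prov = r.provenance
        rows.append({
            "antibody": prov.get("antibody"),
            "mouse": prov.get("mouse"),
            "embedding": prov.get("embedding"),
            "grid": prov.get("grid"),
            "ribbon": prov.get("ribbon"),
            "x": r.particle[0], "y": r.particle[1],
            "d1": r.d1, "d2": r.d2,
            "inside": r.inside, "degenerate": r.degenerate,
            "d_rel": r.d_rel,
        })
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def write_records_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)
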