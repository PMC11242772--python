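import numpy as np
import pytest

from ribbonmap import Midline, RibbonAnnotation, RibbonOutline

# Published fit parameters of the logistic radial profile for the two
# antibody labels (midline count a1, far asymptote a2, half-decay center,
# power p), used as ground truth in evaluation and recovery tests.
A_DOMAIN_PARAMS = dict(a1=72.656, a2=-0.023, center=1.000, p=2.874)
B_DOMAIN_PARAMS = dict(a1=153.587, a2=-0.072, center=1.087, p=3.5594)


@pytest.fixture
def rect_geometry():
    """Rectangular ribbon x in [0, 10], y in [-2, 2] with a straight
    midline along its long axis — the worked example geometry."""
    outline = RibbonOutline([(0, -2), (10, -2), (10, 2), (0, 2)])
    midline = Midline([(0, 0), (10, 0)])
    return outline, midline


@pytest.fixture
def rect_annotation(rect_geometry):
    outline, midline = rect_geometry
    particles = [(5.0, 0.0, "inside"), (5.0, 2.0, "inside"),
                 (5.0, 1.0, "inside"), (5.0, 4.0, "outside")]
    return RibbonAnnotation(
        outline=outline, midpoints=midline, particles=particles,
        nm_per_px=1.2,
        provenance={"antibody": "A", "mouse": "m1", "embedding": "e1",
                    "grid": "g1", "ribbon": "r1", "image": "img1"})


def random_annotation(rng: np.random.Generator) -> RibbonAnnotation:
    """A valid random bar-shaped annotation for round-trip/property tests."""
    from ribbonmap.simulate import SyntheticConfig, generate_ribbon

    cfg = SyntheticConfig(seed=0)
    ribbon = generate_ribbon(cfg, rng)
    n = int(rng.integers(0, 8))
    minx, miny, maxx, maxy = ribbon.outline.polygon.bounds
    pts = np.column_stack([rng.uniform(minx - 20, maxx + 20, n),
                           rng.uniform(miny - 20, maxy + 20, n)])
    classes = rng.choice(["inside", "outside", "unclassified"], n)
    return RibbonAnnotation(
        outline=ribbon.outline, midpoints=ribbon.midline,
        particles=[(float(x), float(y), str(c))
                   for (x, y), c in zip(pts, classes)],
        nm_per_px=float(rng.uniform(0.8, 2.0)) if rng.random() < 0.5 else None,
        provenance={"antibody": "X", "mouse": "m1", "grid": "g1",
                    "ribbon": f"r{rng.integers(1000)}"})
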