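"""Synthetic-data generator: geometry validity, radial density sampling,
label displacement, dataset bookkeeping and determinism."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from conftest import B_DOMAIN_PARAMS
from ribbonmap.annotations import write_annotations
from ribbonmap.simulate import (GradientDensity, InvalidConfigError,
                                LogisticDensity, SyntheticConfig,
                                UniformInsideDensity, displace_labels,
                                generate_dataset, generate_ribbon,
                                gradient_detection_power, sample_drel,
                                sample_true_positions)
from ribbonmap.geometry import batch_relative_distance
from ribbonmap.stats import compute_relative_distances, \
    summarize_inside_outside


class TestGenerateRibbon:
    def test_zero_curvature_is_symmetric_bar(self):
        """With no curvature the outline is a rectangle with end caps and
        every midline vertex is equidistant from the two long sides."""
        cfg = SyntheticConfig(curvature_deg=0.0, seed=0)
        rng = np.random.default_rng(10)
        ribbon = generate_ribbon(cfg, rng)
        pts = ribbon.midline.points
        assert np.ptp(pts[:, 1]) < 1e-9  # straight midline
        ys = ribbon.outline.vertices[:, 1]
        top, bottom = ys.max(), ys.min()
        mid_y = pts[0, 1]
        assert (top - mid_y) == pytest.approx(ribbon.half_width_px, abs=1e-6)
        assert (mid_y - bottom) == pytest.approx(ribbon.half_width_px,
                                                 abs=1e-6)

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_generated_geometry_is_valid(self, seed):
        """Outline simple, positive area, containing the midline, with a
        plausible midpoint count — over many seeds."""
        cfg = SyntheticConfig(seed=seed)
        rng = np.random.default_rng(seed)
        ribbon = generate_ribbon(cfg, rng)
        assert ribbon.outline.polygon.is_valid
        assert ribbon.outline.area > 0
        assert ribbon.outline.polygon.buffer(1e-9).covers(
            ribbon.midline.line)
        assert 5 <= len(ribbon.midline) <= 20

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(seed=0)
        r1 = generate_ribbon(cfg, np.random.default_rng(4))
        r2 = generate_ribbon(cfg, np.random.default_rng(4))
        np.testing.assert_array_equal(r1.outline.vertices,
                                      r2.outline.vertices)
        np.testing.assert_array_equal(r1.midline.points, r2.midline.points)

    def test_width_must_be_below_length(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(ribbon_width_nm=(300, 400),
                            ribbon_length_nm=(300, 600))


class TestDensitySampling:
    def test_uniform_inside_gives_uniform_drel(self):
        """Sampled positions in a straight ribbon give d_rel that a KS test
        cannot distinguish from uniform on [0, 1]."""
        cfg = SyntheticConfig(curvature_deg=0.0, seed=0)
        rng = np.random.default_rng(123)
        ribbon = generate_ribbon(cfg, rng)
        pos = sample_true_positions(ribbon, UniformInsideDensity(), 1000, rng)
        _, _, _, d_rel = batch_relative_distance(pos, ribbon.midline,
                                                 ribbon.outline)
        assert sps.kstest(d_rel, "uniform").pvalue > 0.01

    def test_logistic_density_histogram_matches_model(self):
        """Positions sampled under the logistic model reproduce its d_rel
        density (chi-square goodness of fit)."""
        density = LogisticDensity(**B_DOMAIN_PARAMS, support=4.0)
        cfg = SyntheticConfig(curvature_deg=0.0, seed=0)
        rng = np.random.default_rng(99)
        ribbon = generate_ribbon(cfg, rng)
        n = 4000
        pos = sample_true_positions(ribbon, density, n, rng)
        _, _, _, d_rel = batch_relative_distance(pos, ribbon.midline,
                                                 ribbon.outline)
        edges = np.linspace(0, 4.0, 17)
        observed, _ = np.histogram(d_rel, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.maximum(density(centers), 0)
        expected = n * dens / dens.sum()
        keep = expected > 5
        chi2 = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        pvalue = sps.chi2.sf(chi2, keep.sum() - 1)
        assert pvalue > 0.01

    def test_zero_samples(self):
        cfg = SyntheticConfig(seed=0)
        rng = np.random.default_rng(0)
        ribbon = generate_ribbon(cfg, rng)
        assert sample_true_positions(ribbon, UniformInsideDensity(), 0,
                                     rng).shape == (0, 2)

    def test_invalid_density_rejected(self):
        with pytest.raises(InvalidConfigError):
            LogisticDensity(a1=100, a2=0, center=-1, p=3)
        with pytest.raises(InvalidConfigError):
            GradientDensity("sideways")

    def test_sample_drel_follows_density(self):
        density = LogisticDensity(**B_DOMAIN_PARAMS)
        rng = np.random.default_rng(5)
        v = sample_drel(density, 20000, rng)
        assert v.min() >= 0 and v.max() <= 13
        # mass below the half-decay point should match the model mass
        grid = np.linspace(0, 13, 10001)
        d = density(grid)
        model_frac = np.trapezoid(d[grid <= 1.087], grid[grid <= 1.087]) \
            / np.trapezoid(d, grid)
        got_frac = np.mean(v <= 1.087)
        assert got_frac == pytest.approx(model_frac, abs=0.02)


class TestDisplacement:
    def test_sigma_zero_is_identity(self):
        pos = np.random.default_rng(0).uniform(0, 100, (50, 2))
        out = displace_labels(pos, 0.0, 1.2, np.random.default_rng(1))
        np.testing.assert_array_equal(out, pos)

    def test_mean_radial_displacement_is_rayleigh(self):
        """Isotropic Gaussian displacement of sigma gives mean radial shift
        sigma * sqrt(pi/2)."""
        rng = np.random.default_rng(2)
        pos = np.zeros((10_000, 2))
        out = displace_labels(pos, 10.0, 1.0, rng)  # 1 nm/px: radii in nm
        radii = np.hypot(out[:, 0], out[:, 1])
        assert radii.mean() == pytest.approx(10.0 * np.sqrt(np.pi / 2),
                                             rel=0.02)

    def test_displacement_pushes_particles_off_ribbon(self):
        """With all true positions on the ribbon, displacement produces a
        nonzero observed outside fraction."""
        cfg = SyntheticConfig(seed=8, curvature_deg=0.0,
                              background_rate_per_um2=0.0,
                              displacement_sigma_nm=10.0,
                              n_ribbons=2, n_grids=1, n_mice=1,
                              n_particles=200.0)
        annotations, truth = generate_dataset(cfg)
        assert (truth["d_rel_true"] <= 1).all()  # truly all on the ribbon
        records = compute_relative_distances(annotations)
        outside = sum(not r.inside for r in records)
        assert outside > 0


class TestDataset:
    def test_hierarchy_bookkeeping(self):
        cfg = SyntheticConfig(seed=1, n_mice=3, n_grids=3, n_ribbons=10,
                              n_particles=3.0)
        annotations, truth = generate_dataset(cfg)
        assert len(annotations) == 90
        assert len({a.provenance["ribbon"] for a in annotations}) == 90
        assert set(truth["ribbon"]) <= {a.provenance["ribbon"]
                                        for a in annotations}
        assert {a.provenance["mouse"] for a in annotations} \
            == {"m1", "m2", "m3"}

    def test_clean_conditions_give_100_percent_inside(self):
        cfg = SyntheticConfig(seed=3, displacement_sigma_nm=0.0,
                              background_rate_per_um2=0.0,
                              n_mice=1, n_grids=2, n_ribbons=3,
                              n_particles=20.0)
        annotations, _ = generate_dataset(cfg)
        records = compute_relative_distances(annotations)
        s = summarize_inside_outside(records)
        assert (s["percent_inside"] == 100.0).all()

    def test_same_seed_serializes_identically(self, tmp_path):
        cfg = SyntheticConfig(seed=11, n_mice=1, n_grids=1, n_ribbons=3)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_annotations(generate_dataset(cfg)[0], p1)
        write_annotations(generate_dataset(cfg)[0], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_annotations_roundtrip_through_schema(self, tmp_path):
        from ribbonmap.annotations import read_annotations

        cfg = SyntheticConfig(seed=6, n_mice=1, n_grids=1, n_ribbons=2)
        annotations, _ = generate_dataset(cfg)
        path = tmp_path / "ds.json"
        write_annotations(annotations, path)
        back = read_annotations(path)
        assert len(back) == len(annotations)
        for a, b in zip(annotations, back):
            np.testing.assert_array_equal(a.outline.vertices,
                                          b.outline.vertices)
            assert a.particles == b.particles


class TestEndToEndRecovery:
    def test_pipeline_recovers_generating_profile(self):
        """Generate ~5000 particles under the logistic radial model with
        the published shape parameters, run the full analysis, and recover
        center and power within 10%."""
        density = LogisticDensity(**B_DOMAIN_PARAMS)
        cfg = SyntheticConfig(seed=21, density_model=density,
                              displacement_sigma_nm=0.0,
                              background_rate_per_um2=0.0,
                              n_mice=3, n_grids=3, n_ribbons=6,
                              n_particles=95.0)
        annotations, truth = generate_dataset(cfg)
        assert len(truth) > 4000
        from ribbonmap import RibbonTopographyModel

        res = RibbonTopographyModel.from_annotations(annotations).fit()
        fit = res.fits[cfg.antibody]
        assert fit.converged
        assert fit.center == pytest.approx(B_DOMAIN_PARAMS["center"], rel=0.1)
        assert fit.p == pytest.approx(B_DOMAIN_PARAMS["p"], rel=0.1)

    def test_gradient_models_are_discriminable(self):
        """Center- vs surface-weighted gradients separate above the
        uniform-model null at realistic particle counts."""
        out = gradient_detection_power(n_particles=1500, exponent=1.0,
                                       n_reps=20, seed=3)
        assert out["power"] >= 0.9
        assert out["alt_separations"].mean() > 2 * out["null_threshold"]
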