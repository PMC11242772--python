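"""Group statistics: record computation, inside/outside summaries,
Kruskal-Wallis with a permutation oracle, and Dunn's post hoc test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import random_annotation
from ribbonmap import RibbonAnnotation
from ribbonmap.annotations import records_to_frame
from ribbonmap.geometry import Midline, RibbonOutline
from ribbonmap.stats import (box_stats, compare_groups,
                             compute_relative_distances, dunn_test,
                             summarize_inside_outside)


class TestComputeRelativeDistances:
    def test_worked_rectangle_records(self, rect_annotation):
        records = compute_relative_distances([rect_annotation])
        assert [r.d_rel for r in records] == pytest.approx([0, 1, 0.5, 2.0])
        assert all(r.provenance["grid"] == "g1" for r in records)

    def test_empty_input(self):
        assert compute_relative_distances([]) == []

    def test_record_count_matches_generated_particles(self):
        from ribbonmap.simulate import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(seed=5, n_mice=3, n_grids=3, n_ribbons=1)
        annotations, truth = generate_dataset(cfg)
        records = compute_relative_distances(annotations)
        assert len(records) == len(truth)
        assert len({r.provenance["grid"] for r in records}) == 9

    def test_bad_annotation_skipped_not_fatal(self, rect_annotation, caplog):
        bad = RibbonAnnotation(
            outline=RibbonOutline([(0, 0), (10, 0), (10, 4), (0, 4)]),
            midpoints=Midline([(0, 20), (10, 20)]),  # midline escapes outline
            particles=[(5.0, 2.0, "inside")],
            provenance={"ribbon": "bad"})
        with caplog.at_level("ERROR"):
            records = compute_relative_distances([bad, rect_annotation])
        assert len(records) == 4  # only the valid annotation contributes
        assert any("skipped" in r.message for r in caplog.records)

    def test_class_disagreement_logged(self, rect_geometry, caplog):
        outline, midline = rect_geometry
        ann = RibbonAnnotation(outline=outline, midpoints=midline,
                               particles=[(5.0, 1.0, "outside")],
                               provenance={"ribbon": "r"})
        with caplog.at_level("WARNING"):
            records = compute_relative_distances([ann])
        assert records[0].inside  # recomputed containment wins
        assert any("marked outside" in r.message for r in caplog.records)
        trusted = compute_relative_distances([ann],
                                             trust_annotation_class=True)
        assert not trusted[0].inside


class TestSummaries:
    def make_records(self, drels, grid="g1", ribbon="r1"):
        rows = [{"antibody": "A", "mouse": "m1", "embedding": "e1",
                 "grid": grid, "ribbon": ribbon, "x": 0.0, "y": 0.0,
                 "d1": 1.0, "d2": 1.0, "inside": d <= 1,
                 "degenerate": False, "d_rel": d} for d in drels]
        return pd.DataFrame(rows)

    def test_percent_split(self):
        df = self.make_records([0.2, 0.5, 0.9, 1.7])
        s = summarize_inside_outside(df)
        assert s.loc[0, "percent_inside"] == pytest.approx(75.0)
        assert s.loc[0, "percent_outside"] == pytest.approx(25.0)
        assert s.loc[0, "per_ribbon_inside"] == pytest.approx(3.0)

    def test_all_inside(self):
        s = summarize_inside_outside(self.make_records([0.1, 0.6, 1.0]))
        assert s.loc[0, "percent_inside"] == 100.0
        assert s.loc[0, "percent_outside"] == 0.0

    def test_percentages_sum_to_100_on_synthetic_data(self):
        from ribbonmap.simulate import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(seed=2, n_mice=2, n_grids=2, n_ribbons=3)
        annotations, truth = generate_dataset(cfg)
        records = compute_relative_distances(annotations)
        s = summarize_inside_outside(records)
        np.testing.assert_allclose(
            s["percent_inside"] + s["percent_outside"], 100.0)
        # bookkeeping against the generator's own particle counts
        per_grid = truth.groupby("grid").size()
        got = s.set_index("grid")[["n_inside", "n_outside"]].sum(axis=1)
        assert got.sort_index().equals(per_grid.sort_index())

    def test_box_stats_contract(self):
        v = np.arange(1, 101, dtype=float)
        b = box_stats(v)
        assert b["q05"] == pytest.approx(np.quantile(v, 0.05))
        assert b["q95"] == pytest.approx(np.quantile(v, 0.95))
        assert b["q1"] == pytest.approx(np.quantile(v, 0.25))
        assert b["mean"] == pytest.approx(50.5)
        assert len(b["low_outliers"]) == len(b["high_outliers"]) == 5


class TestGroupComparison:
    def test_identical_groups_no_difference(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.h_statistic == 0.0
        assert res.p_value == 1.0

    def test_extreme_separation_detected(self):
        groups = {"g1": np.arange(1, 10), "g2": np.arange(1, 10) + 0.5,
                  "g3": np.arange(101, 110), "g4": np.arange(101, 110) + 0.5}
        res = compare_groups(groups)
        assert res.p_value < 0.05
        sig = res.significant_pairs()
        assert ("g1", "g3") in sig and ("g2", "g4") in sig
        assert ("g1", "g2") not in sig

    def test_kw_matches_permutation_oracle(self):
        """The Kruskal-Wallis p-value agrees with a permutation null of the
        H statistic within Monte Carlo error (3 groups, n = 5 each)."""
        rng = np.random.default_rng(7)
        samples = {"a": rng.normal(0, 1, 5), "b": rng.normal(0.15, 1, 5),
                   "c": rng.normal(0.3, 1, 5)}
        res = compare_groups(samples)
        pooled = np.concatenate(list(samples.values()))
        h_obs = sps.kruskal(*samples.values()).statistic
        n_perm, count = 10_000, 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            h = sps.kruskal(perm[:5], perm[5:10], perm[10:]).statistic
            count += h >= h_obs
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < mc_err

    def test_dunn_matrix_properties(self):
        rng = np.random.default_rng(0)
        samples = {g: rng.normal(i, 1, 6) for i, g in enumerate("abc")}
        z, p = dunn_test(samples)
        assert np.allclose(z.values, -z.values.T)
        assert ((p.values >= 0) & (p.values <= 1)).all()
        res = compare_groups(samples)
        assert np.allclose(res.p_adjusted.values, res.p_adjusted.values.T)
        assert (res.p_adjusted.values <= 1).all()

    def test_dunn_z_against_direct_formula(self):
        """No-ties case checked against a hand-computed rank-sum z."""
        samples = {"x": [1.0, 2.0, 3.0], "y": [4.0, 5.0, 6.0]}
        z, _ = dunn_test(samples)
        n = 6
        mean_rx, mean_ry = 2.0, 5.0
        se = np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        assert z.at["x", "y"] == pytest.approx((mean_rx - mean_ry) / se)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [1, 2, 3]})
        with pytest.raises(ValueError):
            compare_groups({"a": [1, 2, 3]})
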