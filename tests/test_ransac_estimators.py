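"""End-to-end behaviour of the robust line estimators on planted data."""

from dataclasses import replace

import numpy as np
import pytest

from needlefind import (PlantedLineSpec, RansacConfig, generate_planted_points)
from needlefind.geometry import (LineModel, Point2D, PointSet,
                                 angular_deviation, point_line_distance)
from needlefind.ransac import (detect_single_needle, local_optimize,
                               ransac_baseline, ransac_pretest)


def _planted(eps, seed):
    return generate_planted_points(PlantedLineSpec(outlier_ratio=eps, rng_seed=seed))


class TestBaseline:
    def test_exact_recovery_on_collinear_points(self):
        xy = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0) + 1.0])
        res = ransac_baseline(PointSet(xy), RansacConfig(outlier_ratio=0.0, rng_seed=3))
        assert res.support == 10
        assert np.max(point_line_distance(xy, res.model)) < 1e-9

    def test_planted_support_with_light_contamination(self):
        sample = _planted(0.2, 11)
        cfg = RansacConfig(outlier_ratio=0.2, rng_seed=5)
        res = ransac_baseline(sample.points, cfg)
        n_true = len(sample.inlier_indices)
        assert res.support >= 0.9 * n_true

    def test_deterministic_under_fixed_seed(self):
        sample = _planted(0.4, 8)
        cfg = RansacConfig(outlier_ratio=0.4, rng_seed=77)
        r1 = ransac_baseline(sample.points, cfg)
        r2 = ransac_baseline(sample.points, cfg)
        assert r1.model == r2.model
        assert np.array_equal(r1.inlier_indices, r2.inlier_indices)
        assert r1.sigma == r2.sigma

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            ransac_baseline(PointSet([[0.0, 0.0]]), RansacConfig())

    def test_all_coincident_samples_raise(self):
        xy = np.zeros((10, 2))
        with pytest.raises(ValueError, match="degenerate"):
            ransac_baseline(PointSet(xy), RansacConfig(outlier_ratio=0.0))


class TestPretest:
    def test_clean_data_reduces_to_single_sample(self):
        """At eps = 0 the budget collapses to one iteration and no candidate
        is ever pretested, matching baseline behaviour."""
        xy = np.column_stack([np.arange(20.0), np.arange(20.0)])
        cfg = RansacConfig(outlier_ratio=0.0, rng_seed=4)
        rp = ransac_pretest(PointSet(xy), cfg)
        rb = ransac_baseline(PointSet(xy), cfg)
        assert rp.pretest_rejections == 0
        assert rp.model == rb.model
        assert rp.support == rb.support == 20

    def test_prescreening_skips_most_verifications_when_contaminated(self):
        """At eps = 0.8 fewer than half of the baseline's full-dataset
        verifications remain (the hardware-free speedup)."""
        for seed in range(5):
            sample = _planted(0.8, 100 + seed)
            cfg = RansacConfig(outlier_ratio=0.8, rng_seed=seed)
            rb = ransac_baseline(sample.points, cfg)
            rp = ransac_pretest(sample.points, cfg)
            assert rp.pretest_rejections > 0
            assert rp.full_verifications < 0.5 * rb.full_verifications

    def test_pretest_size_larger_than_dataset_raises(self):
        with pytest.raises(ValueError, match="pretest"):
            ransac_pretest(PointSet(np.random.default_rng(0).normal(size=(10, 2))),
                           RansacConfig(pretest_size=15))


class TestLocalOptimize:
    def test_noiseless_seed_is_kept(self):
        xy = np.column_stack([np.linspace(0, 30, 40), np.zeros(40)])
        cfg = RansacConfig(outlier_ratio=0.0, rng_seed=1)
        seed_res = ransac_baseline(PointSet(xy), cfg)
        out = local_optimize(PointSet(xy), seed_res, cfg)
        assert out.support == seed_res.support == 40
        assert angular_deviation(out.model, seed_res.model) < 1e-9

    def test_usually_improves_angular_accuracy(self):
        """Paired planted-line trials: post-LO deviation <= pre-LO deviation
        in at least 90% of 100 seeded runs."""
        wins = 0
        for seed in range(100):
            sample = _planted(0.5, seed)
            cfg = RansacConfig(outlier_ratio=0.5, rng_seed=seed)
            rng = np.random.default_rng(seed)
            pre = ransac_pretest(sample.points, cfg, rng=rng)
            post = local_optimize(sample.points, pre, cfg, rng=rng)
            b_pre = angular_deviation(pre.model, sample.line)
            b_post = angular_deviation(post.model, sample.line)
            wins += b_post <= b_pre + 1e-12
        assert wins >= 90

    def test_pca_finish_minimises_consensus_sse(self):
        """The final PCA model has no larger orthogonal SSE on its consensus
        than the two-point seed model."""
        sample = _planted(0.3, 21)
        cfg = RansacConfig(outlier_ratio=0.3, rng_seed=21)
        rng = np.random.default_rng(21)
        pre = ransac_pretest(sample.points, cfg, rng=rng)
        post = local_optimize(sample.points, pre, cfg, rng=rng)
        xy = sample.points.xy[post.inlier_indices]
        sse_post = np.sum(point_line_distance(xy, post.model) ** 2)
        sse_seed = np.sum(point_line_distance(xy, pre.model) ** 2)
        assert sse_post <= sse_seed + 1e-9

    def test_never_degrades_selection_criterion(self):
        """LO output never has a worse robust scale than its seed."""
        from needlefind.ransac import robust_sigma_quantile
        for seed in (3, 4, 5):
            sample = _planted(0.6, seed)
            cfg = RansacConfig(outlier_ratio=0.6, rng_seed=seed)
            rng = np.random.default_rng(seed)
            pre = ransac_pretest(sample.points, cfg, rng=rng)
            post = local_optimize(sample.points, pre, cfg, rng=rng)
            s_pre = robust_sigma_quantile(
                point_line_distance(sample.points.xy, pre.model), 2, 0.6)
            s_post = robust_sigma_quantile(
                point_line_distance(sample.points.xy, post.model), 2, 0.6)
            assert s_post <= s_pre + 1e-9

    def test_degenerate_consensus_returns_seed_with_flag(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 40.0], [50.0, 41.0]])
        cfg = RansacConfig(outlier_ratio=0.0, rng_seed=0)
        seed_res = ransac_baseline(PointSet(xy), cfg)
        tiny = replace(seed_res := seed_res, inlier_indices=np.array([0]))
        out = local_optimize(PointSet(xy), tiny, cfg)
        assert out.degenerate_warning


class TestDetectSingleNeedle:
    def test_equals_composition_of_stages(self):
        sample = _planted(0.4, 2)
        cfg = RansacConfig(outlier_ratio=0.4, rng_seed=9)
        composed_rng = np.random.default_rng(9)
        pre = ransac_pretest(sample.points, cfg, rng=composed_rng)
        expected = local_optimize(sample.points, pre, cfg, rng=composed_rng)
        got = detect_single_needle(sample.points, cfg)
        assert got.model == expected.model
        assert np.array_equal(got.inlier_indices, expected.inlier_indices)

    @pytest.mark.parametrize("eps", [0.1, 0.3, 0.5, 0.8])
    def test_planted_line_recovery_across_ratios(self, eps):
        for seed in range(10):
            sample = _planted(eps, 1000 + seed)
            cfg = RansacConfig(outlier_ratio=eps, rng_seed=seed)
            res = detect_single_needle(sample.points, cfg)
            assert angular_deviation(res.model, sample.line) <= 1.0

    def test_inlier_set_matches_ground_truth(self):
        """At eps = 0.5 the recovered inlier set agrees with the generated
        one (Jaccard >= 0.8) for every seed."""
        for seed in range(5):
            sample = _planted(0.5, 2000 + seed)
            cfg = RansacConfig(outlier_ratio=0.5, rng_seed=seed)
            res = detect_single_needle(sample.points, cfg)
            got = set(map(int, res.inlier_indices))
            true = set(map(int, sample.inlier_indices))
            jac = len(got & true) / len(got | true)
            assert jac >= 0.8
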