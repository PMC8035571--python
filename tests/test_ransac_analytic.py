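"""Analytic RANSAC pieces: sample counts, binomial pretest, robust scale,
inlier gate.  Expected values come from independent exact computations
(big-rational binomial tails, direct formula evaluation, brute force)."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from needlefind.geometry import LineModel, Point2D, PointSet, point_line_distance
from needlefind.ransac import (gate_inliers, min_samples,
                               pretest_pass_probability, robust_sigma,
                               robust_sigma_quantile, select_nf)


def exact_tail(n: int, nf: int, eps: Fraction) -> Fraction:
    """P(#inliers >= nf), inlier probability 1-eps, in exact rationals."""
    p = 1 - eps
    return sum(Fraction(comb(n, i)) * p**i * (1 - p)**(n - i)
               for i in range(nf, n + 1))


class TestMinSamples:
    @pytest.mark.parametrize("P,eps,m,Pt,expected", [
        (0.99, 0.0, 2, 1.0, 1),     # no outliers: one sample suffices
        (0.99, 0.5, 2, 1.0, 17),    # ceil(log 0.01 / log 0.75)
        (0.99, 0.5, 2, 0.8, 21),    # pretest-adjusted bound
    ])
    def test_reference_values(self, P, eps, m, Pt, expected):
        assert min_samples(P, eps, m, Pt) == expected

    def test_monotonicity(self):
        grid = np.linspace(0.0, 0.85, 18)
        ks = [min_samples(0.99, e, 2) for e in grid]
        assert all(b >= a for a, b in zip(ks, ks[1:]))
        assert min_samples(0.99, 0.5, 3) >= min_samples(0.99, 0.5, 2)

    @given(eps=st.floats(0.0, 0.9), Pt=st.floats(0.1, 1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pretest_never_cheaper(self, eps, Pt):
        assert min_samples(0.99, eps, 2, Pt) >= min_samples(0.99, eps, 2, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            min_samples(1.0, 0.5, 2)
        with pytest.raises(ValueError):
            min_samples(0.99, 1.0, 2)


class TestPretestPassProbability:
    def test_nf_zero_is_certain(self):
        assert pretest_pass_probability(10, 0, 0.7) == 1.0

    def test_two_point_example(self):
        # 1 - C(2,0) * 0.5^2
        assert pretest_pass_probability(2, 1, 0.5) == pytest.approx(0.75, abs=1e-12)

    def test_matches_exact_rational_tail(self):
        """Float evaluation tracks the exact binomial tail to 1e-12, n <= 30."""
        for n in (5, 15, 30):
            for eps_r in (Fraction(1, 10), Fraction(3, 10), Fraction(1, 2), Fraction(4, 5)):
                for nf in range(0, n + 1, max(1, n // 6)):
                    exact = float(exact_tail(n, nf, eps_r))
                    got = pretest_pass_probability(n, nf, float(eps_r))
                    assert got == pytest.approx(exact, abs=1e-12)

    def test_operating_point(self):
        expected = float(exact_tail(15, 9, Fraction(3, 10)))
        assert pretest_pass_probability(15, 9, 0.3) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8689, abs=5e-5)


class TestSelectNf:
    def test_exhaustive_oracle(self):
        """select_nf returns the largest feasible nf per brute-force scan."""
        for n, eps, pt_min in [(15, 0.3, 0.8), (15, 0.8, 0.8), (10, 0.5, 0.9)]:
            nf, pt = select_nf(n, eps, pt_min)
            feasible = [k for k in range(n + 1)
                        if pretest_pass_probability(n, k, eps) >= pt_min]
            assert nf == max(feasible)
            assert pt == pytest.approx(pretest_pass_probability(n, nf, eps))

    def test_paper_operating_point(self):
        assert select_nf(15, 0.3, 0.8)[0] == 9

    def test_certainty_demands_empty_criterion(self):
        assert select_nf(15, 0.4, 1.0)[0] == 0

    def test_monotone_in_confidence(self):
        nfs = [select_nf(15, 0.3, pt)[0] for pt in (0.5, 0.7, 0.9, 0.99)]
        assert all(b <= a for a, b in zip(nfs, nfs[1:]))


class TestRobustSigma:
    def test_reference_value(self):
        # n=12, m=2, median |d| = 1 -> 1.4826 * 1.5
        r = np.array([1.0] * 12)
        assert robust_sigma(r, 2) == pytest.approx(1.4826 * 1.5, abs=1e-12)

    def test_zero_residuals(self):
        assert robust_sigma(np.zeros(10), 2) == 0.0

    def test_scale_equivariance(self, rng):
        r = rng.normal(size=40)
        assert robust_sigma(3.7 * r, 2) == pytest.approx(3.7 * robust_sigma(r, 2))

    def test_below_validity_raises(self):
        with pytest.raises(ValueError, match="2m"):
            robust_sigma(np.ones(3), 2)

    def test_gaussian_consistency(self):
        """On clean Gaussian residuals the estimate tracks the true scale
        (within 15% over 50 seeds, n = 1000)."""
        target = 2.5 * (1 + 5 / 998)
        for seed in range(50):
            r = np.random.default_rng(seed).normal(0, 2.5, 1000)
            assert robust_sigma(r, 2) == pytest.approx(target, rel=0.15)

    def test_quantile_form_reduces_to_median_at_zero_contamination(self, rng):
        r = rng.normal(size=101)
        assert robust_sigma_quantile(r, 2, 0.0) == pytest.approx(robust_sigma(r, 2))

    def test_quantile_form_tracks_inlier_scale_under_contamination(self):
        """With eps known, the quantile scale ignores a majority of gross
        outliers where the median form cannot."""
        rng = np.random.default_rng(7)
        inl = rng.normal(0, 1.0, 300)
        out = rng.uniform(20, 60, 700) * rng.choice([-1, 1], 700)
        r = np.concatenate([inl, out])
        est = robust_sigma_quantile(r, 2, 0.7)
        assert est == pytest.approx(1.0, rel=0.25)
        assert robust_sigma(r, 2) > 10  # median form breaks down


class TestGateInliers:
    line = LineModel(Point2D(0.0, 0.0), (1.0, 0.0))

    def test_point_on_line_always_inlier(self):
        pts = PointSet([[5.0, 0.0], [1.0, 10.0]])
        assert 0 in gate_inliers(pts, self.line, sigma=0.001)

    def test_boundary(self):
        pts = PointSet([[0.0, 1.96], [0.0, 1.97]])
        idx = gate_inliers(pts, self.line, sigma=1.0, z=1.96)
        assert list(idx) == [0]

    def test_equals_bruteforce_filter(self, rng):
        pts = PointSet(rng.uniform(-10, 10, (200, 2)))
        idx = gate_inliers(pts, self.line, sigma=1.3, z=1.96)
        brute = [i for i in range(200)
                 if point_line_distance(pts.point(i), self.line) <= 1.96 * 1.3]
        assert list(idx) == brute

    def test_zero_sigma_keeps_only_exact_points(self):
        pts = PointSet([[1.0, 0.0], [2.0, 1e-6]])
        assert list(gate_inliers(pts, self.line, sigma=0.0)) == [0]

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gate_inliers(PointSet([[0.0, 0.0]]), self.line, sigma=-1.0)
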