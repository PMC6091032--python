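"""Agreement battery: hand-arithmetic oracles and statistical properties."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from vco2ree import (
    bias_and_sd,
    bland_altman,
    lin_ccc,
    pearson_with_ci,
    percentage_metrics,
    performance_table,
    ratio_band_agreement,
    summarize_agreement,
)
from vco2ree.agreement import PctMode


def _ccc_brute(x, y):
    """Lin's formula evaluated directly, independent of the implementation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = sum((v - mx) ** 2 for v in x) / n
    sy = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx + sy + (mx - my) ** 2)


def _pearson_brute(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


paired = st.integers(min_value=5, max_value=60).flatmap(
    lambda n: st.tuples(
        arrays(float, n, elements=st.floats(500, 4000)),
        arrays(float, n, elements=st.floats(500, 4000)),
    )
)


class TestBiasAndSd:
    def test_identical(self):
        assert bias_and_sd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0)

    def test_constant_shift(self):
        ref = np.array([1500.0, 2000.0, 2500.0])
        assert bias_and_sd(ref + 100, ref) == pytest.approx((100.0, 0.0))

    def test_hand_case(self):
        md, sd = bias_and_sd([1900.0, 2100.0, 2000.0], [2000.0] * 3)
        assert md == pytest.approx(0.0)
        assert sd == pytest.approx(100.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            bias_and_sd([1.0], [1.0])
        with pytest.raises(ValueError):
            bias_and_sd([1.0, 2.0], [1.0])


class TestRatioBands:
    def test_perfect(self):
        ref = [1000.0, 2000.0]
        assert ratio_band_agreement(ref, ref, 0.85, 1.15) == 1.0

    def test_counting(self):
        ref = np.full(5, 1000.0)
        est = np.array([0.80, 0.90, 1.00, 1.10, 1.20]) * 1000
        assert ratio_band_agreement(est, ref, 0.85, 1.15) == pytest.approx(0.6)
        assert ratio_band_agreement(est, ref, 0.95, 1.05) == pytest.approx(0.2)

    def test_closed_endpoints(self):
        assert ratio_band_agreement([850.0], [1000.0], 0.85, 1.15) == 1.0

    def test_nonpositive_ref(self):
        with pytest.raises(ValueError):
            ratio_band_agreement([1.0], [0.0], 0.85, 1.15)


class TestLinCcc:
    def test_perfect_concordance(self):
        x = [1.0, 2.0, 3.0, 4.0]
        ccc, lo, hi = lin_ccc(x, x, ci_method=None)
        assert ccc == pytest.approx(1.0)

    def test_anticoncordance(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        est = -ref + 2 * ref.mean()
        ccc, *_ = lin_ccc(est, ref, ci_method=None)
        assert ccc <= 0

    def test_brute_force_oracle(self):
        est, ref = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 6.0]
        ccc, *_ = lin_ccc(est, ref, ci_method=None)
        assert ccc == pytest.approx(_ccc_brute(est, ref), rel=1e-12)
        assert ccc == pytest.approx(0.65, rel=1e-12)

    def test_bootstrap_ci_brackets_point(self, rng):
        ref = rng.normal(2000, 400, 200)
        est = ref + rng.normal(0, 300, 200)
        ccc, lo, hi = lin_ccc(est, ref, ci_method="bootstrap", n_boot=500, seed=0)
        assert lo < ccc < hi

    def test_fisher_ci_brackets_point(self, rng):
        ref = rng.normal(2000, 400, 200)
        est = ref + rng.normal(0, 300, 200)
        ccc, lo, hi = lin_ccc(est, ref, ci_method="fisher")
        assert -1 < lo < ccc < hi < 1

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            lin_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(paired)
    def test_ccc_bounded_by_pearson(self, xy):
        """Lin's inequality: |CCC| <= |r| on any dataset."""
        est, ref = xy
        if np.all(est == est[0]) or np.all(ref == ref[0]):
            return
        ccc, *_ = lin_ccc(est, ref, ci_method=None)
        r = _pearson_brute(list(est), list(ref))
        assert abs(ccc) <= abs(r) + 1e-10


class TestPearson:
    def test_affine_perfect(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, lo, hi = pearson_with_ci(2 * ref + 5, ref)
        assert r == pytest.approx(1.0)

    def test_shuffled_near_zero(self, rng):
        ref = rng.normal(2000, 400, 2000)
        est = rng.permutation(ref)
        r, *_ = pearson_with_ci(est, ref)
        assert abs(r) < 3 / math.sqrt(2000)

    def test_formula_oracle(self):
        est = [1.0, 4.0, 2.0, 8.0, 5.0]
        ref = [2.0, 3.0, 7.0, 9.0, 5.0]
        r, lo, hi = pearson_with_ci(est, ref)
        assert r == pytest.approx(_pearson_brute(est, ref), rel=1e-12)
        assert lo < r < hi

    @given(paired, st.floats(min_value=0.1, max_value=10))
    def test_positive_scaling_invariance(self, xy, c):
        """Pearson r is exactly invariant under positive rescaling of the
        estimate — why correlation is identical across RQ columns."""
        est, ref = xy
        if np.all(est == est[0]) or np.all(ref == ref[0]):
            return
        r1, *_ = pearson_with_ci(est, ref)
        r2, *_ = pearson_with_ci(c * est, ref)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPercentageMetrics:
    def test_identical(self):
        ref = np.array([1000.0, 2000.0])
        assert percentage_metrics(ref, ref) == (0.0, 0.0)

    def test_constant_overestimate(self):
        ref = np.array([1000.0, 2000.0, 1500.0])
        pe, _ = percentage_metrics(1.10 * ref, ref)
        assert pe == pytest.approx(0.10, rel=1e-12)

    def test_hand_case(self):
        est, ref = [900.0, 1100.0], [1000.0, 1000.0]
        pe, pd_ = percentage_metrics(est, ref)
        assert pe == pytest.approx(0.10, rel=1e-12)
        # brute-force pair-mean definition
        expected = (100 / 950 + 100 / 1050) / 2
        assert pd_ == pytest.approx(expected, rel=1e-12)

    def test_critchley_mode(self):
        est = np.array([1900.0, 2100.0, 2000.0])
        ref = np.full(3, 2000.0)
        pe, _ = percentage_metrics(est, ref, error_mode=PctMode.CRITCHLEY)
        assert pe == pytest.approx(1.96 * 100.0 / 2000.0, rel=1e-12)

    def test_nonpositive_ref(self):
        with pytest.raises(ValueError):
            percentage_metrics([1.0], [-1.0])


class TestBlandAltman:
    def test_identical(self):
        ref = np.array([1000.0, 2000.0, 1500.0])
        res = bland_altman(ref, ref)
        assert res.bias == 0 and res.loa_low == 0 and res.loa_high == 0
        assert np.all(res.points[:, 1] == 0)

    def test_hand_fixture(self):
        est = np.array([10.0, 20.0, 30.0])
        ref = np.array([12.0, 18.0, 33.0])
        res = bland_altman(est, ref)
        sd = math.sqrt(7.0)  # sample SD of [-2, 2, -3]
        assert res.bias == pytest.approx(-1.0)
        assert res.loa_low == pytest.approx(-1 - 1.96 * sd)
        assert res.loa_high == pytest.approx(-1 + 1.96 * sd)
        np.testing.assert_allclose(res.points[:, 0], [11.0, 19.0, 31.5])

    def test_loa_coverage_normal_differences(self, rng):
        """~95% of normally distributed differences fall inside the limits
        of agreement."""
        ref = rng.normal(2000, 400, 10000)
        est = ref + rng.normal(0, 200, 10000)
        res = bland_altman(est, ref)
        inside = np.mean(
            (res.points[:, 1] >= res.loa_low) & (res.points[:, 1] <= res.loa_high)
        )
        assert 0.94 <= inside <= 0.96

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestSummarize:
    def test_nested_bands(self, rng):
        ref = rng.normal(2000, 400, 300)
        est = ref * rng.lognormal(0, 0.15, 300)
        s = summarize_agreement(est, ref, n_boot=200)
        assert s.tight_agreement <= s.agreement <= 1.0
        assert abs(s.ccc) <= abs(s.pearson_r) + 1e-10

    def test_degenerate_constant_estimate(self):
        ref = np.array([1000.0, 1500.0, 2000.0, 2500.0])
        s = summarize_agreement(np.zeros(4), ref)
        assert s.agreement == 0.0 and s.tight_agreement == 0.0
        assert math.isnan(s.pearson_r) and math.isnan(s.ccc)
        assert s.mean_difference == pytest.approx(-ref.mean())


class TestPerformanceTable:
    def test_ordered_as_grid(self, small_paired):
        rows = performance_table(small_paired, n_boot=200)
        assert [s.rq for s in rows] == list(small_paired.rq_grid)

    def test_bias_increases_as_rq_decreases(self, small_paired):
        """The VCO2-only estimate grows as the assumed RQ shrinks, so with a
        fixed reference the mean difference rises monotonically."""
        rows = performance_table(small_paired, n_boot=200)
        biases = [s.mean_difference for s in rows]  # ascending-RQ order
        assert biases == sorted(biases, reverse=True)

    def test_correlation_identical_across_rq(self, small_paired):
        """A fixed RQ rescales the estimate by a positive constant, which
        leaves Pearson r exactly unchanged."""
        rows = performance_table(small_paired, n_boot=200)
        rs = [s.pearson_r for s in rows]
        assert max(rs) - min(rs) < 1e-12

    def test_noisefree_row_at_cohort_rq(self, noisefree_paired):
        rows = performance_table(noisefree_paired, n_boot=200)
        row = {s.rq: s for s in rows}[0.75]
        assert row.mean_difference == pytest.approx(0.0, abs=1e-6)
        assert row.agreement == 1.0 and row.tight_agreement == 1.0
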