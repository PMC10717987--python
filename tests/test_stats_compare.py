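"""Statistical layer: t-tests, normality, point-wise curves, power."""

import numpy as np
import pytest
from scipy import stats as sps

from gaitkin.exceptions import InvalidParameterError
from gaitkin.stats_compare import (independent_t, paired_t, pointwise_compare,
                                   power_n_two_sample, power_two_sample,
                                   shapiro_wilk)

# Reference values computed with R 4.3 shapiro.test()
R_SHAPIRO = [
    ([1, 2, 3, 4, 5, 6, 7, 8, 9], 0.9722884259, 0.9135609537),
    ([2.1, -0.7, 0.3, 1.9, -1.2, 0.05, 3.3, 0.8, -0.4, 1.1, 0.6, -2.2],
     0.9948208277, 0.9999990709),
]


class TestShapiroWilk:
    @pytest.mark.parametrize("x,w_ref,p_ref", R_SHAPIRO)
    def test_matches_r_reference(self, x, w_ref, p_ref):
        res = shapiro_wilk(x)
        assert res.statistic == pytest.approx(w_ref, abs=1e-6)
        assert res.p_value == pytest.approx(p_ref, abs=1e-6)

    def test_too_small_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            shapiro_wilk([1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidParameterError):
            shapiro_wilk([3.0] * 10)


class TestPairedT:
    def test_closed_form_example(self):
        # d = (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    def test_identical_samples_rejected(self):
        with pytest.raises(InvalidParameterError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        r1, r2 = paired_t(a, b), paired_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_agrees_with_scipy_on_random_inputs(self, rng):
        for _ in range(200):
            n = rng.integers(3, 30)
            a, b = rng.normal(0, 2, n), rng.normal(0.3, 2, n)
            ours = paired_t(a, b)
            ref = sps.ttest_rel(a, b)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestIndependentT:
    def test_equal_means_give_t_zero(self):
        res = independent_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_example(self):
        res = independent_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.statistic == pytest.approx(-1.0, abs=1e-12)
        assert res.df == 8

    def test_welch_and_pooled_match_scipy(self, rng):
        for _ in range(100):
            na, nb = rng.integers(3, 20), rng.integers(3, 20)
            a, b = rng.normal(0, 1, na), rng.normal(0.4, 3, nb)
            for equal_var in (True, False):
                ours = independent_t(a, b, equal_var=equal_var)
                ref = sps.ttest_ind(a, b, equal_var=equal_var)
                assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
                assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_double_degenerate_rejected(self):
        with pytest.raises(InvalidParameterError):
            independent_t([2.0, 2.0], [5.0, 5.0])


class TestPointwise:
    def test_large_shift_significant_everywhere(self, rng):
        base = rng.normal(0, 1, (9, 101))
        shifted = base + 10.0 + rng.normal(0, 0.1, (9, 101))
        res = pointwise_compare(base, shifted)
        assert res.n_significant_points == 101

    def test_identical_conditions_count_zero(self, rng):
        base = rng.normal(0, 1, (9, 101))
        res = pointwise_compare(base, base.copy())
        assert res.n_significant_points == 0
        assert np.all(res.p_values == 1.0)

    def test_localized_effect_matches_brute_force_loop(self, rng):
        base = rng.normal(0, 1, (9, 101))
        other = base + rng.normal(0, 0.5, (9, 101))
        other[:, 20:41] += 4.0  # effect only in 20-40 % of the cycle
        res = pointwise_compare(base, other, alpha=0.05)
        expected_mask = np.zeros(101, dtype=bool)
        for k in range(101):
            expected_mask[k] = paired_t(base[:, k], other[:, k]).p_value < 0.05
        np.testing.assert_array_equal(res.significant_mask, expected_mask)
        assert res.n_significant_points == expected_mask.sum()
        assert expected_mask[20:41].mean() > 0.9  # concentrated in the window

    def test_subject_mismatch_rejected(self, rng):
        a = {f"s{k}": rng.normal(size=101) for k in range(5)}
        b = {f"t{k}": rng.normal(size=101) for k in range(5)}
        with pytest.raises(InvalidParameterError, match="subject"):
            pointwise_compare(a, b)

    def test_correction_reduces_counts(self, rng):
        base = rng.normal(0, 1, (9, 101))
        other = base + rng.normal(0.35, 1.0, (9, 101))
        raw = pointwise_compare(base, other)
        holm = pointwise_compare(base, other, correction="holm")
        assert holm.n_significant_points <= raw.n_significant_points


class TestPower:
    def test_reproduces_study_sample_size(self):
        assert power_n_two_sample(1.37, alpha=0.05, power=0.80, tails=1) == 16

    def test_two_tailed_needs_more_subjects(self):
        assert power_n_two_sample(1.37, alpha=0.05, power=0.80, tails=2) == 20

    def test_huge_effect_boundary(self):
        assert power_n_two_sample(10.0, alpha=0.05, power=0.80, tails=1) == 4

    def test_returned_n_is_minimal(self):
        for d in (0.8, 1.37, 2.0):
            total = power_n_two_sample(d, tails=1)
            n = total // 2
            assert power_two_sample(n, d, tails=1) >= 0.80
            if n > 2:
                assert power_two_sample(n - 1, d, tails=1) < 0.80

    def test_monotonicity(self):
        assert power_n_two_sample(1.0, tails=2) >= power_n_two_sample(1.5, tails=2)
        assert power_n_two_sample(1.0, alpha=0.01) >= power_n_two_sample(1.0, alpha=0.10)
        assert power_n_two_sample(1.0, power=0.95) >= power_n_two_sample(1.0, power=0.80)

    @pytest.mark.parametrize("kwargs", [{"effect_size_d": 0.0}, {"effect_size_d": -1.0},
                                        {"effect_size_d": 1.0, "alpha": 1.5},
                                        {"effect_size_d": 1.0, "power": 0.0}])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            power_n_two_sample(**kwargs)
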