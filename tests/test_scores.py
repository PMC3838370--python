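"""Unit and property tests for the per-variable subgroup statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import betainc

from fishersum import (
    ContingencyTable2x2,
    TwoGroupVector,
    bartlett_pvalue,
    excess_kurtosis,
    fisher10_pvalue,
    fisher_cutpoint,
    fisher_sum,
    ort,
    outlier_sum,
    padge_score,
    permutation_pvalue_fs,
    score_all,
    t_test_onesided,
)
from fishersum.scores import METHOD_ORDER, exceedance_table, fisher_exact_upper_tail


class TestTwoGroupVector:
    def test_rejects_small_groups(self):
        with pytest.raises(ValueError, match="at least 2"):
            TwoGroupVector([1.0], [1.0, 2.0])

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="non-finite"):
            TwoGroupVector([1.0, np.nan], [1.0, 2.0])


class TestFisherCutpoint:
    def test_order_statistic_by_hand(self):
        dis = [0, 0, 0, 0, 0, 0, 0, 0, 5, 10]
        assert fisher_cutpoint(dis, 0.1) == 5  # m = 9th smallest

    def test_constant_input_no_strict_exceedance(self):
        dis = np.full(12, 3.7)
        cut = fisher_cutpoint(dis, 0.1)
        assert cut == 3.7
        assert np.sum(dis > cut) == 0

    def test_exact_exceedance_count_for_distinct_values(self, rng):
        dis = rng.normal(size=70)
        assert len(np.unique(dis)) == 70
        cut = fisher_cutpoint(dis, 0.1)
        assert np.sum(dis > cut) == 7  # m = 63

    @pytest.mark.parametrize("n", range(2, 40))
    def test_at_most_qfrac_exceed(self, n, rng):
        dis = rng.normal(size=n)
        cut = fisher_cutpoint(dis, 0.1)
        assert np.sum(dis > cut) <= math.floor(0.1 * n + 1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fisher_cutpoint([])


class TestFisherSum:
    def test_disease_specific_subgroup_by_hand(self):
        v = TwoGroupVector([0] * 10, [0] * 8 + [5, 10])
        assert fisher_sum(v).value == pytest.approx(1.0)

    def test_non_disease_specific_pattern_penalized_to_zero(self):
        vals = [0] * 8 + [5, 10]
        v = TwoGroupVector(vals, vals)
        assert fisher_sum(v).value == pytest.approx(0.0)

    def test_translation_invariance(self, random_vector):
        v = random_vector
        shifted = TwoGroupVector(v.ctrl + 100.0, v.dis + 100.0)
        assert fisher_sum(shifted).value == pytest.approx(
            fisher_sum(v).value, rel=1e-9, abs=1e-12
        )

    def test_positive_homogeneity(self, random_vector):
        v = random_vector
        scaled = TwoGroupVector(3.5 * v.ctrl, 3.5 * v.dis)
        assert fisher_sum(scaled).value == pytest.approx(3.5 * fisher_sum(v).value)

    def test_clamp_modes(self):
        # control exceedances outweigh disease ones -> negative under the
        # term-clamp reading, zero under the score-clamp reading
        v = TwoGroupVector([0] * 8 + [5, 20], [0] * 8 + [5, 10])
        assert fisher_sum(v, clamp="terms").value == pytest.approx(-1.0)
        assert fisher_sum(v, clamp="score").value == 0.0
        with pytest.raises(ValueError):
            fisher_sum(v, clamp="bogus")

    def test_explicit_weights_override_defaults(self):
        v = TwoGroupVector([0] * 10, [0] * 8 + [5, 10])
        assert fisher_sum(v, w_ctrl=1.0, w_dis=1.0).value == pytest.approx(10.0)


class TestFisher10:
    def test_upper_tail_by_product_formula(self):
        # P(X >= 7) with all 7 draws from the 70 disease items among 140
        table = ContingencyTable2x2(7, 0, 63, 70)
        expected = math.prod((70 - i) / (140 - i) for i in range(7))
        assert fisher_exact_upper_tail(table) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.7e-3, rel=0.02)

    def test_symmetric_table_not_significant(self):
        assert fisher_exact_upper_tail(ContingencyTable2x2(5, 5, 25, 25)) >= 0.5

    def test_maximal_under_representation(self):
        assert fisher_exact_upper_tail(ContingencyTable2x2(0, 30, 30, 0)) == 1.0

    def test_matches_scipy_fisher_exact(self, rng):
        # independent route: scipy's conditional exact test on the same table
        for _ in range(25):
            v = TwoGroupVector(rng.normal(size=15), rng.normal(2.0, 1.0, size=12))
            t = exceedance_table(v)
            ours = fisher10_pvalue(v).value
            ref = stats.fisher_exact(
                [[t.n11, t.n12], [t.n21, t.n22]], alternative="greater"
            ).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)


class TestOutlierSum:
    def test_no_exceedance_by_hand(self):
        v = TwoGroupVector([-1, 1, -1, 1], [-1, 1, -1, 1])
        assert outlier_sum(v).value == 0.0

    def test_single_outlier_by_hand(self):
        v = TwoGroupVector([1, 2, 3, 4, 5], [1, 2, 3, 4, 50])
        # pooled med 3, MAD 1.4826; only (50-3)/1.4826 exceeds q75+IQR
        assert outlier_sum(v).value == pytest.approx((50 - 3) / 1.4826, rel=1e-4)

    def test_affine_invariance(self, random_vector):
        v = random_vector
        mapped = TwoGroupVector(2.5 * v.ctrl - 7.0, 2.5 * v.dis - 7.0)
        assert outlier_sum(mapped).value == pytest.approx(
            outlier_sum(v).value, rel=1e-9, abs=1e-12
        )

    def test_zero_mad_degenerate(self):
        score = outlier_sum(TwoGroupVector([0, 0, 0, 0, 1], [0, 0, 0, 0, 2]))
        assert score.value == 0.0
        assert score.warning is not None


class TestOrt:
    def test_empty_outlier_set(self):
        v = TwoGroupVector([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert ort(v).value == 0.0

    def test_regression_fixture_by_hand(self):
        # threshold q75(C)+IQR(C) = 0.75; O = {1, 1, 10}; denominator =
        # median of pooled |x - own median| = 1  =>  ORT = 12
        v = TwoGroupVector([0, 0, 0, 1, -1, 1, -1, 0], [0, 0, 0, 1, -1, 1, -1, 10])
        assert ort(v).value == pytest.approx(12.0)

    def test_translation_invariance(self, random_vector):
        v = random_vector
        shifted = TwoGroupVector(v.ctrl + 42.0, v.dis + 42.0)
        assert ort(shifted).value == pytest.approx(ort(v).value, rel=1e-9, abs=1e-12)


class TestPadge:
    def test_identical_groups_score_zero(self, rng):
        x = rng.normal(size=40)
        assert padge_score(TwoGroupVector(x, x)).value == 0.0

    def test_pure_shift_reduces_to_sum_of_log_pvalues(self, rng):
        # dis = ctrl + delta: every percentile subset shifts identically, so
        # each ratio term is exactly delta/delta = 1 and the score reduces
        # to the sum of Bonferroni-corrected -log10 p-values.
        ctrl = rng.normal(size=50)
        dis = ctrl + 1.0
        expected = 0.0
        for pct in (80, 85, 90):
            c = ctrl[ctrl >= np.percentile(ctrl, pct)]
            d = dis[dis >= np.percentile(dis, pct)]
            p = stats.ttest_ind(d, c, equal_var=True, alternative="greater").pvalue
            expected += -math.log10(min(1.0, 3 * p))
        assert padge_score(TwoGroupVector(ctrl, dis)).value == pytest.approx(expected)

    def test_translation_invariance(self, random_vector):
        v = random_vector
        shifted = TwoGroupVector(v.ctrl - 13.0, v.dis - 13.0)
        assert padge_score(shifted).value == pytest.approx(
            padge_score(v).value, rel=1e-9, abs=1e-12
        )


class TestKurtosis:
    def test_alternating_values_closed_form(self):
        # m2 = 1, m4 = 1 -> b2 = 1 -> excess = -2
        v = TwoGroupVector([-1, 1] * 5, [-1, 1] * 5)
        assert excess_kurtosis(v).value == pytest.approx(-2.0)

    def test_large_normal_sample_near_zero(self, rng):
        x = rng.normal(size=100_000)
        v = TwoGroupVector(x[:50_000], x[50_000:])
        assert abs(excess_kurtosis(v).value) < 0.05

    def test_affine_invariance(self, random_vector):
        v = random_vector
        mapped = TwoGroupVector(0.3 * v.ctrl + 5.0, 0.3 * v.dis + 5.0)
        assert excess_kurtosis(mapped).value == pytest.approx(
            excess_kurtosis(v).value, rel=1e-9
        )

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            excess_kurtosis(TwoGroupVector([1.0, 1.0], [1.0, 1.0]))


def _bartlett_oracle(a, b):
    # closed-form two-group Bartlett statistic, chi-square with 1 df
    na, nb = len(a), len(b)
    sa, sb = np.var(a, ddof=1), np.var(b, ddof=1)
    sp = ((na - 1) * sa + (nb - 1) * sb) / (na + nb - 2)
    num = (na + nb - 2) * math.log(sp) - (na - 1) * math.log(sa) - (nb - 1) * math.log(sb)
    corr = 1 + (1 / (na - 1) + 1 / (nb - 1) - 1 / (na + nb - 2)) / 3
    return stats.chi2.sf(num / corr, 1)


class TestBartlett:
    def test_equal_sample_variances_give_p_one(self, rng):
        x = rng.normal(size=30)
        v = TwoGroupVector(x, x + 5.0)  # identical spread, shifted location
        assert bartlett_pvalue(v).value == pytest.approx(1.0)

    def test_strong_variance_ratio_matches_closed_form(self, rng):
        a = rng.normal(0, 1, size=50)
        b = rng.normal(0, 4, size=50)
        p = bartlett_pvalue(TwoGroupVector(a, b)).value
        assert p == pytest.approx(_bartlett_oracle(a, b), rel=1e-9)
        assert p < 1e-6

    def test_symmetry_under_group_swap(self, random_vector):
        v = random_vector
        swapped = TwoGroupVector(v.dis, v.ctrl)
        assert bartlett_pvalue(swapped).value == pytest.approx(
            bartlett_pvalue(v).value, rel=1e-12
        )

    def test_degenerate_variances(self):
        both = bartlett_pvalue(TwoGroupVector([1.0, 1.0], [2.0, 2.0]))
        assert both.value == 1.0 and both.warning is not None
        one = bartlett_pvalue(TwoGroupVector([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]))
        assert one.value == 0.0 and one.warning is not None


class TestTTest:
    def test_identical_groups_give_half(self, rng):
        x = rng.normal(size=20)
        assert t_test_onesided(TwoGroupVector(x, x)).value == pytest.approx(0.5)

    def test_closed_form_example(self):
        # t = sqrt(6), df = 6; one-sided p via the regularized incomplete beta
        v = TwoGroupVector([0, 0, 1, 1], [1, 1, 2, 2])
        t, df = math.sqrt(6), 6
        expected = 0.5 * betainc(df / 2, 0.5, df / (df + t * t))
        assert t_test_onesided(v).value == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.025, abs=5e-4)

    def test_one_sided_direction_and_complement(self, rng):
        ctrl = rng.normal(1.0, 1.0, size=15)
        dis = rng.normal(0.0, 1.0, size=15)
        p = t_test_onesided(TwoGroupVector(ctrl, dis)).value
        assert p > 0.5
        p_opposite = t_test_onesided(TwoGroupVector(dis, ctrl)).value
        assert p + p_opposite == pytest.approx(1.0, abs=1e-12)


class TestPermutationPvalue:
    def test_constant_data_gives_one(self):
        v = TwoGroupVector([1.0] * 6, [1.0] * 6)
        assert permutation_pvalue_fs(v, n_perm=119, seed=1) == 1.0

    def test_bounds_by_construction(self, random_vector):
        p = permutation_pvalue_fs(random_vector, n_perm=119, seed=2)
        assert 0.0 < p <= 1.0

    def test_requires_enough_permutations(self, random_vector):
        with pytest.raises(ValueError):
            permutation_pvalue_fs(random_vector, n_perm=50)

    def test_null_calibration_uniform(self, rng):
        # p-values over many no-subgroup variables should look uniform
        pvals = []
        for i in range(150):
            v = TwoGroupVector(rng.normal(size=20), rng.normal(size=20))
            pvals.append(permutation_pvalue_fs(v, n_perm=119, seed=1000 + i))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestScoreAll:
    def test_all_methods_in_deterministic_order(self, random_vector):
        scored = score_all(random_vector)
        assert [s.method for s in scored] == list(METHOD_ORDER)

    def test_empty_method_set(self, random_vector):
        assert score_all(random_vector, []) == []

    def test_unknown_method_errors(self, random_vector):
        with pytest.raises(KeyError):
            score_all(random_vector, ["fisher_sum", "copa"])

    def test_degenerate_variable_flags_only_affected_methods(self):
        v = TwoGroupVector([0, 0, 0, 0, 1], [0, 0, 0, 0, 2])
        by_name = {s.method: s for s in score_all(v)}
        assert by_name["outlier_sum"].warning is not None
        assert by_name["outlier_sum"].value == 0.0
        for m in ("fisher_sum", "t_test", "bartlett", "kurtosis"):
            assert np.isfinite(by_name[m].value)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), shift=st.floats(-50, 50))
def test_all_statistics_translation_invariant(seed, shift):
    """Adding a constant to every observation changes no statistic."""
    r = np.random.default_rng(seed)
    v = TwoGroupVector(r.normal(size=18), r.normal(0.5, 1.5, size=22))
    w = TwoGroupVector(v.ctrl + shift, v.dis + shift)
    for func in (
        fisher_sum,
        fisher10_pvalue,
        outlier_sum,
        ort,
        padge_score,
        excess_kurtosis,
        bartlett_pvalue,
        t_test_onesided,
    ):
        assert func(w).value == pytest.approx(func(v).value, rel=1e-6, abs=1e-9)
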