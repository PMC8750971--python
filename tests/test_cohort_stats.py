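from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from cniscore.cohort_stats import (
    bh_adjust,
    cutoff_table,
    format_percent,
    one_sample_t_power,
    one_sample_t_sample_size,
    pairwise_comparisons,
    pearson_correlation,
    roc,
    welch_t_test,
    wilcoxon_rank_sum,
)


class TestRoc:
    def test_perfect_separation(self):
        res = roc([1, 2, 3], [11, 12, 13])
        assert res.auc == pytest.approx(1.0)
        assert res.youden_sensitivity == 1.0
        assert res.youden_specificity == 1.0

    def test_overlapping_groups_auc_seven_ninths(self):
        res = roc([1, 2, 3], [2, 3, 4])
        assert res.auc == pytest.approx(7 / 9)

    def test_auc_equals_mann_whitney(self, rng):
        ctrl = rng.normal(0, 1, 25)
        case = rng.normal(1, 1, 25)
        res = roc(ctrl, case)
        u = stats.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
        assert res.auc == pytest.approx(u / (25 * 25))

    def test_auc_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        ctrl = rng.normal(0, 1, 30)
        case = rng.normal(0.8, 1.2, 20)
        res = roc(ctrl, case)
        y = np.r_[np.zeros(30), np.ones(20)]
        expected = sklearn_metrics.roc_auc_score(y, np.r_[ctrl, case])
        assert res.auc == pytest.approx(expected)

    def test_step_function_monotonicity(self, rng):
        scores = rng.integers(0, 50, 40).astype(float)
        res = roc(scores[:20], scores[20:])
        assert (np.diff(res.sensitivity) <= 1e-12).all()
        assert (np.diff(res.specificity) >= -1e-12).all()

    def test_auc_invariant_under_monotone_transform(self, rng):
        ctrl = rng.exponential(10, 30)
        case = rng.exponential(30, 30)
        assert roc(ctrl, case).auc == pytest.approx(roc(np.log(ctrl), np.log(case)).auc)

    def test_youden_tie_breaks_to_lowest_threshold(self):
        # J = 0.5 at both 1.5 and 2.5; the lower threshold wins
        res = roc([1, 2], [2, 3])
        assert res.youden_threshold == pytest.approx(1.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc([], [1.0])


class TestCutoffTable:
    def test_abstract_count_arithmetic(self):
        # positives 21/23, 36/42, 19/22 -> pooled 76/87 -> 87%
        groups = {
            "primary": [30.0] * 21 + [10.0] * 2,
            "plat": [30.0] * 36 + [10.0] * 6,
            "nonplat": [30.0] * 19 + [10.0] * 3,
        }
        table = cutoff_table([5.0] * 10, groups, [24.0])
        row = table.loc[24.0]
        assert row["sensitivity_primary"] == pytest.approx(21 / 23)
        assert row["sensitivity_pooled"] == pytest.approx(76 / 87)
        assert format_percent(row["sensitivity_pooled"]) == 87
        assert format_percent(row["sensitivity_primary"]) == 91
        assert format_percent(row["sensitivity_plat"]) == 86

    def test_degenerate_cutoffs(self):
        table = cutoff_table([5, 6], {"g": [7, 8]}, [0.0, 100.0])
        assert table.loc[0.0, "sensitivity_pooled"] == 1.0
        assert table.loc[0.0, "specificity"] == 0.0
        assert table.loc[100.0, "sensitivity_pooled"] == 0.0
        assert table.loc[100.0, "specificity"] == 1.0

    def test_consistent_with_roc_at_youden(self, rng):
        ctrl = rng.normal(10, 3, 50)
        case = rng.normal(20, 5, 30)
        res = roc(ctrl, case)
        table = cutoff_table(ctrl, {"case": case}, [res.youden_threshold])
        assert table.iloc[0]["sensitivity_case"] == pytest.approx(res.youden_sensitivity)
        assert table.iloc[0]["specificity"] == pytest.approx(res.youden_specificity)

    def test_empty_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            cutoff_table([1.0], {"g": [2.0]}, [])


def _exact_rank_sum_p(a, b):
    """Exhaustive-enumeration two-sided p for the rank-sum statistic."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    observed = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= abs(observed - mu) - 1e-9:
            count += 1
    return count / total


class TestWilcoxonRankSum:
    def test_identical_groups(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_exact_small_case(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6)

    def test_exact_matches_enumeration(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 6)
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(_exact_rank_sum_p(a, b), abs=1e-12)

    def test_approximation_close_to_enumeration(self, rng):
        a = rng.normal(0, 1, 6)
        b = np.r_[rng.normal(1, 1, 5), a[0]]  # inject a tie to force asymptotic
        _, p = wilcoxon_rank_sum(a, b)
        assert p == pytest.approx(_exact_rank_sum_p(a, b), abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 30)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestPearson:
    def test_perfect_linear(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0, 1, 20)
        r, _ = pearson_correlation(x, y)
        expected = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert r == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separation_limit(self):
        eps = 1e-6
        _, p = welch_t_test([0, eps, 0, eps], [1, 1 + eps, 1, 1 + eps])
        assert p < 1e-9

    def test_direction_agrees_with_permutation(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        t, p = welch_t_test(a, b)
        pooled = np.r_[a, b]
        obs = a.mean() - b.mean()
        perm = [
            pooled[idx].mean() - np.delete(pooled, idx).mean()
            for idx in (rng.permutation(20)[:10] for _ in range(2000))
        ]
        p_perm = np.mean(np.abs(perm) >= abs(obs))
        assert t < 0
        assert p == pytest.approx(p_perm, abs=0.05)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1, 2])


class TestSampleSize:
    def test_study_design_returns_66(self):
        assert one_sample_t_sample_size(2.0, 4.0, 0.01, 0.95) == 66

    def test_larger_effect_needs_fewer_patients(self):
        n_small = one_sample_t_sample_size(4.0, 4.0, 0.01, 0.95)
        assert n_small < 66

    def test_returned_n_is_minimal(self):
        n = one_sample_t_sample_size(2.0, 4.0, 0.01, 0.95)
        assert one_sample_t_power(n, 0.5, 0.01) >= 0.95
        assert one_sample_t_power(n - 1, 0.5, 0.01) < 0.95

    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"sigma": 0.0}, {"power": 0.005},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            one_sample_t_sample_size(**{"mean_difference": 2.0, "sigma": 4.0,
                                        "alpha": 0.01, "power": 0.95, **kwargs})


class TestPairwise:
    def test_bh_applied_across_all_pairs(self, rng):
        groups = {g: rng.normal(i, 1, 12) for i, g in enumerate("abc")}
        table = pairwise_comparisons(groups)
        assert len(table) == 3
        np.testing.assert_allclose(
            table["p_adjusted"], bh_adjust(table["p"].to_numpy())
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_comparisons({"a": [1, 2]})
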