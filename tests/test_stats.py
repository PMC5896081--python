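import math

import numpy as np
import pytest
from scipy import stats as sps

from rvolcano import (GroupDesign, WeightMatrix, analyze, bonferroni,
                      call_differential, kernel_weights, log2_fold_change,
                      p_value, t_statistic, weighted_group_stats)
from rvolcano.simulate import SimulationDesign, inject_outliers, simulate_dataset

from conftest import make_dataset


def unit_weights(m):
    return WeightMatrix(np.ones_like(m.values), 0.0)


class TestWeightedGroupStats:
    def test_unit_weights_reduce_to_textbook_moments(self):
        rng = np.random.default_rng(5)
        m, d = make_dataset(rng.normal(20, 5, size=(10, 12)), 7)
        s = weighted_group_stats(m, unit_weights(m), d)
        ctrl, dis = m.values[:, :7], m.values[:, 7:]
        np.testing.assert_allclose(s.mean_control, ctrl.mean(axis=1), rtol=1e-12)
        np.testing.assert_allclose(s.mean_disease, dis.mean(axis=1), rtol=1e-12)
        np.testing.assert_allclose(s.var_control, ctrl.var(axis=1, ddof=1), rtol=1e-12)
        np.testing.assert_allclose(s.var_disease, dis.var(axis=1, ddof=1), rtol=1e-12)
        pooled = (6 * ctrl.var(axis=1, ddof=1) + 4 * dis.var(axis=1, ddof=1)) / 10
        np.testing.assert_allclose(s.pooled_var, pooled, rtol=1e-12)

    def test_group_size_denominator_forced_arithmetic(self):
        m, d = make_dataset([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], 3)
        w = WeightMatrix(np.array([[1.0, 1.0, 1e-320, 1.0, 1.0, 1.0]]), 0.5)
        s = weighted_group_stats(m, w, d, weight_denominator="group_size")
        # printed Step-1 estimator: divisor is the raw group size g1
        assert s.mean_control[0] == pytest.approx(1.0, abs=1e-12)

    def test_sum_weights_denominator_ignores_downweighted_entry(self):
        m, d = make_dataset([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], 3)
        w = WeightMatrix(np.array([[1.0, 1.0, 1e-320, 1.0, 1.0, 1.0]]), 0.5)
        s = weighted_group_stats(m, w, d)
        assert s.mean_control[0] == pytest.approx(1.5, abs=1e-12)

    def test_shape_mismatch_rejected(self, toy_dataset):
        m, d = toy_dataset
        with pytest.raises(ValueError, match="shape"):
            weighted_group_stats(m, WeightMatrix(np.ones((2, 2)), 0.0), d)


class TestLog2FoldChange:
    @pytest.mark.parametrize("md, mc, expected", [
        (4.0, 4.0, 0.0),
        (8.0, 4.0, 1.0),
    ])
    def test_intensity_ratio(self, md, mc, expected):
        assert log2_fold_change(md, mc) == pytest.approx(expected, abs=1e-15)

    def test_non_positive_mean_is_undefined(self):
        assert math.isnan(log2_fold_change(-1.0, 4.0))
        assert math.isnan(log2_fold_change(4.0, 0.0))

    def test_log2_scale_is_difference_of_means(self):
        assert log2_fold_change(8.0, 4.0, data_scale="log2") == 4.0
        assert log2_fold_change(-1.0, 4.0, data_scale="log2") == -5.0


class TestTStatistic:
    def test_pooled_hand_example(self):
        m, d = make_dataset([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], 3)
        s = weighted_group_stats(m, unit_weights(m), d)
        t, df = t_statistic(s, d)
        assert t[0] == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert df[0] == 4.0
        # orientation: control minus disease, same as scipy with that order
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6])
        assert t[0] == pytest.approx(ref.statistic, rel=1e-12)

    def test_identical_groups_give_zero(self):
        m, d = make_dataset([[2.0, 3.0, 4.0, 2.0, 3.0, 4.0]], 3)
        s = weighted_group_stats(m, unit_weights(m), d)
        t, _ = t_statistic(s, d)
        assert t[0] == 0.0

    def test_welch_equals_pooled_for_balanced_equal_variances(self):
        rng = np.random.default_rng(2)
        ctrl = rng.normal(0, 1, 6)
        m, d = make_dataset(np.concatenate([ctrl, ctrl + 3.0])[None, :], 6)
        s = weighted_group_stats(m, unit_weights(m), d)
        t_p, _ = t_statistic(s, d, "pooled")
        t_w, _ = t_statistic(s, d, "welch")
        assert t_w[0] == pytest.approx(t_p[0], rel=1e-12)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(9)
        m, d = make_dataset(rng.normal(10, 3, size=(4, 11)), 6)
        s = weighted_group_stats(m, unit_weights(m), d)
        t, df = t_statistic(s, d, "welch")
        ref = sps.ttest_ind(m.values[:, :6], m.values[:, 6:], axis=1, equal_var=False)
        np.testing.assert_allclose(t, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(df, ref.df, rtol=1e-12)

    def test_degenerate_rows(self):
        m, d = make_dataset([[5.0] * 6, [5.0, 5.0, 5.0, 7.0, 7.0, 7.0]], 3)
        s = weighted_group_stats(m, unit_weights(m), d)
        t, df = t_statistic(s, d)
        assert t[0] == 0.0
        assert t[1] == -np.inf
        assert p_value(t, df)[1] == 0.0


class TestPValue:
    def test_symmetry_and_limits(self):
        assert p_value(0.0, 10.0) == 1.0
        assert p_value(1e6, 10.0) < 1e-30

    def test_known_quantile(self):
        # t_{0.975, 4} = 2.776: two-sided p = 0.050
        assert p_value(2.776, 4.0) == pytest.approx(0.0500, abs=5e-4)

    def test_upper_tail_is_half_of_two_sided_for_positive_t(self):
        assert p_value(1.7, 12.0, tail="upper") == pytest.approx(
            p_value(1.7, 12.0) / 2, rel=1e-12)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            p_value(1.0, 0.0)


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni([0.01]), [0.01])
        np.testing.assert_allclose(bonferroni([0.02, 0.5]), [0.04, 1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        assert np.all(bonferroni(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])


class TestCallDifferential:
    @pytest.mark.parametrize("p, fc, expected", [
        (0.04, 1.5, True),
        (0.04, 1.0, False),    # strict inequality on the fold-change
        (0.05, 3.0, False),    # strict inequality on the p-value
        (0.06, 3.0, False),
        (0.04, float("nan"), False),
    ])
    def test_step3_rule(self, p, fc, expected):
        assert call_differential([p], [fc])[0] == expected


class TestAnalyze:
    def test_lambda_zero_matches_independent_classical_pipeline(self):
        rng = np.random.default_rng(17)
        m, d = make_dataset(rng.lognormal(3, 0.4, size=(12, 11)), 6)
        table = analyze(m, d, 0.0)
        ctrl, dis = m.values[:, :6], m.values[:, 6:]
        ref = sps.ttest_ind(ctrl, dis, axis=1)
        np.testing.assert_allclose(table.t_stats, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(table.p_values, ref.pvalue, rtol=1e-12)
        fc = np.log2(dis.mean(axis=1) / ctrl.mean(axis=1))
        np.testing.assert_allclose(table.log2_fc, fc, rtol=1e-12)
        assert table.method_tag == "CVP"

    def test_row_order_permutation_permutes_results(self):
        rng = np.random.default_rng(21)
        m, d = make_dataset(rng.lognormal(3, 0.4, size=(9, 10)), 5)
        perm = rng.permutation(9)
        m_perm, _ = make_dataset(m.values[perm], 5)
        t_full = analyze(m, d, lam=0.7)
        t_perm = analyze(m_perm, d, lam=0.7)
        np.testing.assert_allclose(t_perm.t_stats, t_full.t_stats[perm], rtol=1e-12)
        np.testing.assert_allclose(t_perm.p_values, t_full.p_values[perm], rtol=1e-12)

    def test_row_independence_under_subsetting(self):
        rng = np.random.default_rng(22)
        m, d = make_dataset(rng.lognormal(3, 0.4, size=(8, 10)), 5)
        sub, _ = make_dataset(m.values[:3], 5)
        t_full = analyze(m, d, lam=1.2)
        t_sub = analyze(sub, d, lam=1.2)
        np.testing.assert_allclose(t_sub.t_stats, t_full.t_stats[:3], rtol=1e-12)

    def test_single_outlier_distorts_robust_t_less_than_classical(self):
        """A gross outlier (3x the row mean) on a genuine-signal row moves the
        kernel-weighted t far less than the classical t.

        Each statistic is compared against its own clean-data value: that
        isolates the influence of the contamination on the estimator.  (On a
        pure-null row no estimator can win near-always, because the classical
        contaminated t is bounded near -sqrt((g-1)/g), which the clean null t
        crosses by chance.)
        """
        wins = 0
        n_rep = 200
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            row = rng.normal(10, 1, size=30)
            row[15:] += 3.0  # true disease-control difference
            m, d = make_dataset(row[None, :], 15)
            bad = row.copy()
            bad[17] = 3 * row.mean()
            mb, _ = make_dataset(bad[None, :], 15)
            d_rvp = abs(analyze(mb, d, 1.0).t_stats[0] - analyze(m, d, 1.0).t_stats[0])
            d_cvp = abs(analyze(mb, d, 0.0).t_stats[0] - analyze(m, d, 0.0).t_stats[0])
            wins += d_rvp < d_cvp
        assert wins >= 0.95 * n_rep

    def test_auto_lambda_on_clean_simulated_data_reduces_to_classical(self):
        m, d, _, _ = simulate_dataset(SimulationDesign(seed=3))
        table = analyze(m, d, "auto", data_scale="log2")
        assert table.lambda_used == 0.0
        assert table.cv_result is not None
        assert table.method_tag == "CVP"

    def test_adjusted_calling_uses_bonferroni(self):
        rng = np.random.default_rng(30)
        base = rng.normal(10, 1, size=(20, 12))
        base[0, 6:] += 8.0  # one strong, honest signal
        m, d = make_dataset(base, 6)
        raw = analyze(m, d, 0.0, data_scale="log2")
        adj = analyze(m, d, 0.0, data_scale="log2", adjusted_calling=True)
        assert adj.differential.sum() <= raw.differential.sum()
        assert adj.results[0].p_adjusted >= adj.results[0].p_value
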