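"""Gated two-sample workflow, exact Mann-Whitney, summary tests, OLS lines."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retinoscope as rs


def exact_mw_two_sided(x, y):
    """Exhaustive-enumeration oracle for the two-sided Mann-Whitney p value."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u1_of(idx):
        r1 = sum(ranks[pooled[i]] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    observed = u1_of(range(n1))
    mean_u = n1 * (len(pooled) - n1) / 2
    stats = [u1_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    dev = abs(observed - mean_u)
    extreme = sum(1 for u in stats if abs(u - mean_u) >= dev - 1e-9)
    return extreme / len(stats)


class TestNormalityGate:
    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(5)
        passed = sum(all(rs.normality_gate(rng.normal(size=50), rng.normal(size=50))) for _ in range(100))
        assert passed >= 90

    def test_lognormal_samples_usually_fail(self):
        rng = np.random.default_rng(6)
        failed = sum(not rs.normality_gate(np.exp(rng.normal(size=50) * 1.5), rng.normal(size=50))[0] for _ in range(100))
        assert failed >= 90

    def test_constant_sample_counts_as_non_normal(self):
        assert rs.normality_gate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])[0] is False

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            rs.normality_gate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_agrees_with_enumeration_for_all_small_sizes(self):
        rng = np.random.default_rng(11)
        for n1 in range(2, 9):
            for n2 in range(2, 9):
                if n1 + n2 > 10:
                    continue
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                _, _, p = rs.mann_whitney(x, y)
                assert p == pytest.approx(exact_mw_two_sided(x, y), abs=1e-12), (n1, n2)

    def test_separated_triples_textbook_case(self):
        u1, u2, p = rs.mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u1 == 0.0
        assert u2 == 9.0
        assert p == pytest.approx(0.1)

    def test_u_values_sum_to_n1_n2(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=8), rng.normal(size=6)
        u1, u2, _ = rs.mann_whitney(x, y)
        assert u1 + u2 == 48.0

    def test_identical_samples_give_p_one(self):
        x = [2.0, 2.0, 2.0, 2.0]
        _, _, p = rs.mann_whitney(x, x)
        assert p == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12, unique=True),
           st.lists(st.floats(-50, 50), min_size=3, max_size=12, unique=True))
    def test_symmetry_under_group_swap(self, x, y):
        """Swapping the groups swaps U1/U2 and leaves p unchanged."""
        u1, u2, p = rs.mann_whitney(x, y)
        v1, v2, q = rs.mann_whitney(y, x)
        assert (u1, u2) == (v2, v1)
        assert p == pytest.approx(q, abs=1e-12)


class TestTwoSampleCompare:
    def test_equal_samples_not_significant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        res = rs.two_sample_compare(x, x.copy())
        assert res.p_two_tailed == pytest.approx(1.0)
        assert not res.significant

    def test_nonnormal_path_reports_medians_and_u(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(size=30) * 1.5)
        y = np.exp(rng.normal(size=25) * 1.5 + 1.0)
        res = rs.two_sample_compare(x, y)
        assert res.test_name == "mann_whitney"
        assert res.U_first_group is not None and res.U_second_group is not None
        assert 0 <= res.U_first_group <= 30 * 25

    def test_bonferroni_blocks_marginal_p(self):
        # Raw p ~ 0.03 with m = 2 comparisons must not be called significant.
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = np.exp(rng.normal(size=25))
            y = np.exp(rng.normal(size=25) + 0.5)
            res2 = rs.two_sample_compare(x, y, m_comparisons=2)
            if 0.025 < res2.p_two_tailed < 0.05:
                assert not res2.significant
                assert rs.two_sample_compare(x, y, m_comparisons=1).significant
                return
        pytest.fail("no draw landed in the marginal p band")

    def test_bonferroni_monotonicity(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=15), rng.normal(1.2, 1, size=15)
        for m in (2, 3, 5):
            if rs.two_sample_compare(x, y, m_comparisons=m).significant:
                assert rs.two_sample_compare(x, y, m_comparisons=m - 1).significant

    def test_welch_equals_student_for_balanced_equal_sd(self):
        s1 = rs.SampleSummary(n=12, mean=5.0, sd=2.0)
        s2 = rs.SampleSummary(n=12, mean=6.0, sd=2.0)
        t_s, _, p_s = rs.t_from_summary(s1, s2, equal_var=True)
        t_w, _, p_w = rs.t_from_summary(s1, s2, equal_var=False)
        assert abs(p_s - p_w) < 1e-6
        assert abs(t_s - t_w) < 1e-9


class TestSummaryT:
    def test_identical_summaries_give_p_one(self):
        s = rs.SampleSummary(n=10, mean=5.0, sd=1.0)
        t, _, p = rs.t_from_summary(s, s)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_central_locomotion_summaries(self):
        # Published open-field central locomotion: 426 +/- 156 cm (n = 13)
        # vs 262 +/- 106 cm (n = 9); pooled t must land near the printed
        # p = 0.012 (SDs are rounded).
        t, df, p = rs.t_from_summary(
            rs.SampleSummary(n=13, mean=426.0, sd=156.0),
            rs.SampleSummary(n=9, mean=262.0, sd=106.0),
            equal_var=True,
        )
        assert df == 20
        assert 0.010 <= p <= 0.016

    def test_matches_raw_sample_t(self):
        rng = np.random.default_rng(15)
        from scipy import stats as sps
        for _ in range(100):
            x = rng.normal(size=rng.integers(5, 20))
            y = rng.normal(0.3, 1.3, size=rng.integers(5, 20))
            for equal_var in (True, False):
                t_raw, _ = sps.ttest_ind(x, y, equal_var=equal_var)
                t_sum, _, _ = rs.t_from_summary(
                    rs.SampleSummary.from_sample(x), rs.SampleSummary.from_sample(y), equal_var=equal_var
                )
                assert abs(t_raw - t_sum) < 1e-9

    def test_degenerate_variances_rejected(self):
        s = rs.SampleSummary(n=5, mean=1.0, sd=0.0)
        with pytest.raises(ValueError):
            rs.t_from_summary(s, s)


class TestPaired:
    def test_zero_differences_give_p_one(self):
        res = rs.paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_two_tailed == 1.0

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            rs.paired_compare([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError):
            rs.paired_compare([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_power_against_planted_ratio(self):
        # True treated/control ratio 0.6 with SD 0.2 at n = 5: the paired t
        # should reject in well over half of replicates at alpha = 0.05.
        rng = np.random.default_rng(21)
        rejections = 0
        for _ in range(500):
            ctr = rng.uniform(0.5, 1.5, size=5)
            vpa = ctr * rng.normal(0.6, 0.2, size=5)
            if rs.paired_compare(vpa, ctr).significant:
                rejections += 1
        assert rejections / 500 >= 0.60


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = rs.linear_fit(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.adj_R2 == pytest.approx(1.0)

    def test_independent_y_gives_near_zero_adj_r2(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=2000)
        fit = rs.linear_fit(x, rng.normal(size=2000))
        assert abs(fit.adj_R2) < 0.01

    def test_duplicated_data_same_line(self):
        rng = np.random.default_rng(31)
        x, y = rng.normal(size=20), rng.normal(size=20)
        f1 = rs.linear_fit(x, y)
        f2 = rs.linear_fit(np.tile(x, 2), np.tile(y, 2))
        assert f2.slope == pytest.approx(f1.slope, rel=1e-12)
        assert f2.intercept == pytest.approx(f1.intercept, rel=1e-12)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(32)
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(size=40)
        fit = rs.linear_fit(x, y)
        model = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(model.params[1], rel=1e-9)
        assert fit.adj_R2 == pytest.approx(model.rsquared_adj, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            rs.linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
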