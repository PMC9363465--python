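"""Unit and property tests for the statistical primitives.

Worked examples were computed by hand (enumeration / closed forms) and the
implementations are cross-checked against scipy, statsmodels and lifelines
as independent oracles on random data.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ferroscore import stats as fstats


class TestWilcoxon:
    def test_full_ties_give_p_one(self):
        res = fstats.wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5
        assert res.p_value == 1.0

    def test_exact_enumeration_small_sample(self):
        # all C(4,2)=6 rank assignments; U=0 occurs once per tail
        res = fstats.wilcoxon_ranksum([1, 2], [3, 4])
        assert res.method.endswith("exact")
        assert res.p_value == pytest.approx(2 / 6)

    def test_complete_separation_counts_u(self):
        res = fstats.wilcoxon_ranksum([10], [1, 2, 3])
        assert res.statistic == 3.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fstats.wilcoxon_ranksum([], [1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_normal_approx(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(0.4, 1, size=25)
        ours = fstats.wilcoxon_ranksum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_and_normal_paths_agree_loosely(self):
        # sanity band: the two p computations should not diverge wildly
        rng = np.random.default_rng(3)
        for _ in range(25):
            x, y = rng.normal(size=4), rng.normal(size=5)
            exact = fstats.wilcoxon_ranksum(x, y).p_value
            approx = fstats.wilcoxon_ranksum(x, y, exact_max_n=0).p_value
            assert abs(exact - approx) < 0.05


class TestChisq:
    def test_printed_contingency_table(self):
        # 22/9 vs 11/31-20 responder split; Yates-corrected p prints as 0.01
        res = fstats.chisq_2x2(22, 9, 11, 20, yates=True)
        assert round(res.p_value, 2) == 0.01

    def test_uncorrected_closed_form(self):
        res = fstats.chisq_2x2(22, 9, 11, 20, yates=False)
        n = 62
        expected = n * (22 * 20 - 9 * 11) ** 2 / (31 * 31 * 33 * 29)
        assert res.statistic == pytest.approx(expected)

    def test_identical_proportions_null(self):
        res = fstats.chisq_2x2(10, 10, 10, 10)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fstats.chisq_2x2(0, 0, 5, 5)

    def test_matches_scipy(self):
        ours = fstats.chisq_2x2(13, 7, 4, 18, yates=True)
        ref = sps.chi2_contingency([[13, 7], [4, 18]], correction=True)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)


class TestSpearman:
    def test_monotone_pairs(self):
        assert fstats.spearman([1, 2, 3], [10, 20, 30]).statistic == 1.0
        assert fstats.spearman([1, 2, 3], [30, 20, 10]).statistic == -1.0

    def test_hand_computed_rho(self):
        # sum d^2 = 4 -> rho = 1 - 24/60 = 0.6
        assert fstats.spearman([1, 2, 3, 4], [2, 1, 4, 3]).statistic == pytest.approx(0.6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            fstats.spearman([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, 40).astype(float)
        y = x + rng.normal(size=40)
        ours = fstats.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestBHFDR:
    def test_step_up_suffix_min(self):
        q = fstats.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal(self):
        assert fstats.bh_fdr([0.03])[0] == pytest.approx(0.03)
        assert np.allclose(fstats.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fstats.bh_fdr([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(50)
        ours = fstats.bh_fdr(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_p_and_preserves_order(self, p):
        q = fstats.bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-15) and np.all(q <= 1)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestKaplanMeier:
    def test_no_censoring_is_one_minus_ecdf(self):
        km = fstats.km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        km = fstats.km_estimate([1, 2, 3], [0, 0, 0])
        assert km.survival.size == 0 and km.survival_at(5.0) == 1.0

    def test_censoring_at_event_time_in_risk_set(self):
        # censored subject at t=2 stays at risk for the t=2 events
        km = fstats.km_estimate([1, 2, 2, 3], [1, 0, 1, 1])
        assert np.allclose(km.survival, [3 / 4, 1 / 2, 0.0])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        t = rng.exponential(1, 60)
        e = rng.integers(0, 2, 60)
        km = fstats.km_estimate(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        for tt, s in zip(km.times, km.survival):
            assert s == pytest.approx(
                float(ref.survival_function_at_times(tt).iloc[0])
            )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            fstats.km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1] * 2
        g = [0] * 4 + [1] * 4
        res = fstats.logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_accumulated_statistic(self):
        # O-E and hypergeometric variance accumulated by hand: chi2 = 49/17
        res = fstats.logrank_test([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        assert res.statistic == pytest.approx(49 / 17)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fstats.logrank_test([1, 2], [1, 1], [0, 0])

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        t = rng.exponential(1, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        ours = fstats.logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.statistic == pytest.approx(ref.test_statistic)
        assert ours.p_value == pytest.approx(ref.p_value)


class TestCox:
    def test_symmetric_data_zero_beta(self):
        # swapping groups maps the data to itself, so the MLE sits at 0
        t = [1, 1, 2, 2, 3, 3]
        e = [1, 1, 1, 1, 0, 0]
        x = [0, 1, 0, 1, 0, 1]
        fit = fstats.cox_ph(t, e, x)
        assert abs(fit.beta[0]) < 1e-6

    def test_closed_form_stationary_point(self):
        # partial-likelihood stationary point solves 2u^2 = 1, u = e^beta
        fit = fstats.cox_ph([1, 2, 3], [1, 1, 1], [1, 0, 1])
        assert fit.converged
        assert fit.beta[0] == pytest.approx(-np.log(2) / 2, abs=1e-8)
        assert fit.hazard_ratio[0] == pytest.approx(2 ** -0.5, abs=1e-8)

    def test_monotone_likelihood_flagged(self):
        fit = fstats.cox_ph([1, 2, 3, 4], [1, 1, 1, 1], [4, 3, 2, 1])
        assert not fit.converged
        assert fit.diagnostic != ""

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            fstats.cox_ph([1, 2, 3], [1, 1, 1], [2, 2, 2])

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines(self, ties):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-0.5 * x[:, 0] + 0.3 * x[:, 1]))
        e = rng.integers(0, 2, n)
        e[0] = 1
        fit = fstats.cox_ph(t, e, x, ties=ties)
        df = pd.DataFrame({"t": t, "e": e, "x0": x[:, 0], "x1": x[:, 1]})
        ref = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron ties
        if ties == "efron":
            assert np.allclose(fit.beta, ref.params_.to_numpy(), atol=1e-5)
            assert np.allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-5)

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(8, 25)
            t = rng.exponential(1, n) + rng.random(n) * 1e-9
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e.sum() == 0 or g.sum() in (0, n):
                continue
            lr = fstats.logrank_test(t, e, g)
            sc = fstats.cox_score_test(t, e, g)
            assert abs(lr.statistic - sc.statistic) < 1e-8
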