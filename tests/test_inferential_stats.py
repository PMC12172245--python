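"""Welch t, Wilcoxon rank-sum, average-variance d, and the JZS Bayes factor.

The deterministic expected values come from the published summary tables of
the motivating two-group study (35 patients with borderline personality
disorder vs 50 healthy controls).
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from coopbattery.inferential_stats import (
    GroupSummary,
    bf_entry_point_comparison,
    cohens_d_avg,
    jzs_ttest_bf,
    pooled_t_from_summary,
    summarize,
    welch_t,
    wilcoxon_ranksum,
)

# published (M, SD, N) group summaries: label -> (patients, controls, printed t, printed d)
PRINTED = {
    "age": (GroupSummary(25.8, 5.58, 35), GroupSummary(24.88, 5.43, 50), 0.756, -0.167),
    "mini_q": (GroupSummary(34.03, 12.12, 35), GroupSummary(35.74, 9.91, 50), -0.689, -0.155),
    "bdi_ii": (GroupSummary(27.743, 12.363, 35), GroupSummary(3.720, 4.071, 50), 11.083, 2.610),
    "lpfs": (GroupSummary(35.629, 5.309, 35), GroupSummary(18.840, 5.068, 50), 14.618, 3.235),
    "pid5bf": (GroupSummary(37.571, 8.859, 35), GroupSummary(13.020, 7.789, 50), 13.207, 2.943),
    "svo_g": (GroupSummary(32.421, 7.127, 29), GroupSummary(35.579, 5.203, 50), -2.085, -0.506),
    "dg": (GroupSummary(4.457, 0.980, 35), GroupSummary(4.780, 0.582, 50), -1.745, -0.400),
}


class TestWelch:
    @pytest.mark.parametrize("label", ["age", "mini_q", "bdi_ii", "lpfs", "pid5bf"])
    def test_reproduces_published_t(self, label):
        a, b, t_printed, _ = PRINTED[label]
        res = welch_t(a, b)
        assert res.statistic == pytest.approx(t_printed, abs=0.005)

    def test_published_age_df_and_ci(self):
        a, b, _, _ = PRINTED["age"]
        res = welch_t(a, b)
        # printed df came from unrounded raw data; rounded summaries shift it ~0.01
        assert res.df == pytest.approx(72.035, abs=0.05)
        assert res.ci_low == pytest.approx(-1.505, abs=0.005)
        assert res.ci_high == pytest.approx(3.345, abs=0.005)

    def test_identical_summaries_give_zero(self):
        g = GroupSummary(5.0, 1.0, 20)
        res = welch_t(g, g)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_raw_vectors_equal_their_summaries(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1.3, 40)
        r1 = welch_t(x, y)
        r2 = welch_t(summarize(x), summarize(y))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
        assert r1.df == pytest.approx(r2.df, rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=25), rng.normal(0.5, 2.0, size=35)
        res = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_zero_variance_rejected(self):
        g = GroupSummary(5.0, 0.0, 10)
        with pytest.raises(ValueError, match="zero variance"):
            welch_t(g, g)

    def test_type_one_error_calibration(self):
        """Null rejections at alpha = 0.05 stay within 0.05 +/- 0.01."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(0, 1, 35)
            y = rng.normal(0, 1, 50)
            if welch_t(x, y).p < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.01


class TestCohensD:
    @pytest.mark.parametrize("label", list(PRINTED))
    def test_reproduces_published_d(self, label):
        """Average-variance standardiser matches every printed effect size.

        Printed signs follow the reporting tool's internal group order, so
        the comparison is on magnitude; table rows where the printed sign
        matches the patients-minus-controls difference are also sign-checked.
        """
        a, b, _, d_printed = PRINTED[label]
        d = cohens_d_avg(a, b)
        assert abs(d) == pytest.approx(abs(d_printed), abs=0.002)

    def test_signed_values_of_task_rows(self):
        a, b, _, d_printed = PRINTED["svo_g"]
        assert cohens_d_avg(a, b) == pytest.approx(d_printed, abs=0.002)
        a, b, _, d_printed = PRINTED["bdi_ii"]
        assert cohens_d_avg(a, b) == pytest.approx(d_printed, abs=0.002)

    def test_equal_means_give_zero(self):
        assert cohens_d_avg(GroupSummary(3, 1, 10), GroupSummary(3, 2, 10)) == 0.0


class TestWilcoxon:
    def test_identical_multisets_give_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = wilcoxon_ranksum(x, list(x))
        assert res.statistic == 0.0
        assert res.effect_size == 0.0

    def test_no_overlap_matches_closed_form(self):
        """With x entirely above y and no ties, z has a closed form."""
        x = np.arange(11.0, 21.0)
        y = np.arange(1.0, 11.0)
        n1 = n2 = 10
        n = n1 + n2
        w_max = n1 * (n1 + 2 * n2 + 1) / 2.0  # x holds the top ranks
        mu = n1 * (n + 1) / 2.0
        sigma = math.sqrt(n1 * n2 * (n + 1) / 12.0)
        res = wilcoxon_ranksum(x, y)
        assert res.statistic == pytest.approx((w_max - mu) / sigma, rel=1e-12)
        assert res.effect_size == pytest.approx(abs(res.statistic) / math.sqrt(n))

    def test_permutation_invariance_within_groups(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(1.0, 1.0, size=15)
        r1 = wilcoxon_ranksum(x, y)
        r2 = wilcoxon_ranksum(rng.permutation(x), rng.permutation(y))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_scipy_with_ties(self):
        x = [1, 2, 2, 3, 5, 5, 8]
        y = [2, 3, 3, 4, 5, 9]
        res = wilcoxon_ranksum(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_tied_documented_path(self):
        res = wilcoxon_ranksum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0
        assert res.p == 1.0


class TestJzsBayesFactor:
    def test_published_bf01_from_summaries(self):
        """Pooled-t reconstruction reproduces the published BF01 values."""
        pm_a = GroupSummary(0.264, 0.101, 24)
        pm_b = GroupSummary(0.287, 0.211, 44)
        assert jzs_ttest_bf(a=pm_a, b=pm_b).bf01 == pytest.approx(3.49, abs=0.05)
        dg_a, dg_b, _, _ = PRINTED["dg"]
        assert jzs_ttest_bf(a=dg_a, b=dg_b).bf01 == pytest.approx(0.92, abs=0.05)
        svo_a, svo_b, _, _ = PRINTED["svo_g"]
        assert jzs_ttest_bf(a=svo_a, b=svo_b).bf01 == pytest.approx(0.47, abs=0.05)

    def test_dual_entry_point_comparison(self):
        """The Welch-t and pooled-t routes are both reported and differ."""
        pm_a = GroupSummary(0.264, 0.101, 24)
        pm_b = GroupSummary(0.287, 0.211, 44)
        cmp = bf_entry_point_comparison(-0.592, pm_a, pm_b)
        assert cmp["bf01_from_summaries"] == pytest.approx(3.49, abs=0.05)
        assert cmp["bf01_from_printed_t"] == pytest.approx(3.34, abs=0.05)
        assert cmp["pooled_t"] == pytest.approx(-0.502, abs=0.002)

    def test_bf_at_zero_t_is_maximal_for_null(self):
        b0 = jzs_ttest_bf(0.0, 20, 25)
        assert b0.bf01 > 1.0
        for t in (0.5, 1.0, 2.0, 4.0):
            assert jzs_ttest_bf(t, 20, 25).bf01 < b0.bf01

    def test_monotone_decreasing_bf01_in_abs_t(self):
        vals = [jzs_ttest_bf(t, 30, 30).bf01 for t in (0.0, 1.0, 2.0, 3.0, 5.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_reciprocal_identity(self):
        res = jzs_ttest_bf(1.7, 18, 22)
        assert res.bf01 * res.bf10 == pytest.approx(1.0, rel=1e-12)

    def test_symmetry_in_t_sign(self):
        assert jzs_ttest_bf(2.0, 15, 20).bf10 == pytest.approx(
            jzs_ttest_bf(-2.0, 15, 20).bf10, rel=1e-9
        )

    def test_against_noncentral_t_quadrature_oracle(self):
        """Independent route: marginal noncentral-t likelihood over the
        Cauchy effect prior, integrated over delta rather than g."""
        t, n1, n2 = 2.0, 30, 30
        r = math.sqrt(2) / 2
        N = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2

        def integrand(d):
            return stats.nct.pdf(t, nu, d * math.sqrt(N)) * stats.cauchy.pdf(d, scale=r)

        num, _ = integrate.quad(integrand, -np.inf, np.inf, limit=400)
        oracle = num / stats.t.pdf(t, nu)
        got = jzs_ttest_bf(t, n1, n2).bf10
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_pooled_t_reconstruction(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)
        ref = stats.ttest_ind(x, y, equal_var=True)
        got = pooled_t_from_summary(summarize(x), summarize(y))
        assert got == pytest.approx(ref.statistic, rel=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jzs_ttest_bf(float("nan"), 10, 10)
        with pytest.raises(ValueError):
            jzs_ttest_bf()
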