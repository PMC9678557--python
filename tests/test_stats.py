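"""Unit and property tests for the first-principles statistics routines."""

import itertools

import numpy as np
import pytest
import scipy.stats
import statsmodels.api as sm

from tonguemetrics.stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    logistic_fit,
    logistic_univariate_2x2,
    mann_whitney_u,
    roc_auc,
    roc_auc_binary,
    spearman,
    two_sample_t,
    two_sample_t_data,
)

from conftest import GREASY, THICK, TOOTH, WHITE


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, stat, p",
        [
            (GREASY, 51.7172, 6.410e-13),
            (THICK, 42.0765, 8.779e-11),
            (TOOTH, 5.2301, 0.022),
        ],
    )
    def test_printed_contingency_values(self, table, stat, p):
        res = chi_square_2x2(table)
        assert res.statistic == pytest.approx(stat, abs=5e-4)
        # agreement at the precision each p-value is printed with
        assert res.p_value == pytest.approx(p, rel=5e-3, abs=5e-4)

    def test_independence_gives_zero(self):
        res = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy(self, rng):
        for _ in range(50):
            cells = rng.integers(1, 60, size=4)
            t = ContingencyTable2x2(*map(int, cells))
            ours = chi_square_2x2(t)
            ref = scipy.stats.chi2_contingency(
                [[t.a, t.b], [t.c, t.d]], correction=False
            )
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_yates_matches_scipy(self):
        ours = chi_square_2x2(TOOTH, yates=True)
        ref = scipy.stats.chi2_contingency([[15, 6], [25, 34]], correction=True)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_transposition_invariance(self, rng):
        cells = [int(v) for v in rng.integers(1, 40, size=4)]
        a, b, c, d = cells
        s1 = chi_square_2x2(ContingencyTable2x2(a, b, c, d)).statistic
        s2 = chi_square_2x2(ContingencyTable2x2(d, c, b, a)).statistic
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="degenerate margin"):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestUnivariateLogistic:
    @pytest.mark.parametrize(
        "table, odds, lo, hi, p",
        [
            (GREASY, 107.667, 20.352, 569.573, 3.688e-08),
            (WHITE, 18.857, 6.123, 58.079, 3.100e-07),
        ],
    )
    def test_printed_odds_ratios(self, table, odds, lo, hi, p):
        fit = logistic_univariate_2x2(table)
        assert fit.odds_ratios[0] == pytest.approx(odds, abs=5e-4)
        assert fit.ci_low[0] == pytest.approx(lo, abs=5e-4)
        assert fit.ci_high[0] == pytest.approx(hi, abs=5e-4)
        assert fit.p_values[0] == pytest.approx(p, rel=5e-3)

    def test_balanced_table_is_null(self):
        fit = logistic_univariate_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert fit.coefficients[0] == 0.0
        assert fit.odds_ratios[0] == 1.0

    def test_zero_cell_raises_unless_corrected(self):
        t = ContingencyTable2x2(10, 0, 5, 10)
        with pytest.raises(ValueError, match="separation"):
            logistic_univariate_2x2(t)
        fit = logistic_univariate_2x2(t, haldane=True)
        assert np.isfinite(fit.odds_ratios[0])


class TestLogisticFit:
    def test_saturated_model_matches_cross_product(self):
        """An IRLS fit on expanded 2x2 data must agree with the closed form."""
        t = GREASY
        y = np.r_[np.ones(t.a + t.c), np.zeros(t.b + t.d)]
        x = np.r_[np.ones(t.a), np.zeros(t.c), np.ones(t.b), np.zeros(t.d)]
        fit = logistic_fit(y, np.column_stack([np.ones_like(x), x]))
        closed = logistic_univariate_2x2(t)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(closed.coefficients[0], abs=1e-8)
        assert fit.standard_errors[1] == pytest.approx(closed.standard_errors[0], abs=1e-8)

    def test_matches_statsmodels(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.integers(0, 2, n)])
        beta = np.array([-0.5, 1.0, 0.7])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        ours = logistic_fit(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert ours.coefficients == pytest.approx(ref.params, abs=1e-6)
        assert ours.standard_errors == pytest.approx(ref.bse, abs=1e-6)

    def test_parameter_recovery(self, rng):
        n = 5000
        x = rng.standard_normal(n)
        eta = -1.0 + 1.5 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_fit(y, np.column_stack([np.ones(n), x]))
        assert fit.converged
        assert fit.coefficients == pytest.approx([-1.0, 1.5], abs=0.1)

    def test_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = logistic_fit(y, np.column_stack([np.ones(20), x]))
        assert not fit.converged

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_fit(np.ones(10), np.ones((10, 1)))


class TestMannWhitney:
    def test_identical_samples_centered(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 8.0  # n1*n2/2
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_disjoint_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.method == "mann-whitney-exact"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_enumeration_all_small_sizes(self, rng):
        """Exact path equals scipy's full enumeration for every n1+n2 <= 10."""
        for n1, n2 in itertools.product(range(1, 9), repeat=2):
            if n1 + n2 > 10:
                continue
            for _ in range(5):
                pooled = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float))
                x, y = pooled[:n1], pooled[n1:]
                ours = mann_whitney_u(x, y)
                ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
                assert ours.method == "mann-whitney-exact"
                assert ours.statistic == ref.statistic
                assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_path_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 8, size=30).astype(float)
        y = rng.integers(1, 9, size=25).astype(float)
        ours = mann_whitney_u(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_u([], [1.0])


class TestTwoSampleT:
    def test_printed_age_comparison(self):
        res = two_sample_t(34.10, 11.03, 40, 33.13, 8.47, 40)
        assert res.p_value == pytest.approx(0.660, abs=5e-4)

    def test_equal_means_null(self):
        res = two_sample_t(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_raw_data_matches_scipy(self, rng):
        x, y = rng.standard_normal(20) + 0.5, rng.standard_normal(25)
        ours = two_sample_t_data(x, y)
        ref = scipy.stats.ttest_ind(x, y, equal_var=True)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)


class TestSpearman:
    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_perfect_monotone(self, sign):
        x = np.arange(10.0)
        res = spearman(x, sign * x**3)
        assert res.statistic == pytest.approx(sign, abs=1e-14)

    def test_matches_rank_pearson_oracle_with_ties(self, rng):
        """Midrank handling equals rank-then-Pearson to 1e-12 on tied data."""
        for _ in range(200):
            x = rng.integers(0, 6, size=20).astype(float)
            y = rng.integers(0, 6, size=20).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            oracle = np.corrcoef(scipy.stats.rankdata(x), scipy.stats.rankdata(y))[0, 1]
            assert spearman(x, y).statistic == pytest.approx(oracle, abs=1e-12)

    def test_p_matches_scipy(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        ours = spearman(x, y)
        ref = scipy.stats.spearmanr(x, y)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRoc:
    @pytest.mark.parametrize(
        "counts, auc",
        [((38, 40, 6, 40), 0.900), ((34, 40, 5, 40), 0.8625)],
    )
    def test_printed_binary_marker_auc(self, counts, auc):
        assert roc_auc_binary(*counts).auc == pytest.approx(auc, abs=5e-4)

    def test_independent_marker_is_half(self):
        assert roc_auc_binary(10, 40, 10, 40).auc == 0.5

    def test_perfect_scores(self):
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        assert roc_auc(labels.astype(float), labels).auc == 1.0

    def test_binary_scores_reduce_to_counts_form(self):
        labels = np.r_[np.ones(40), np.zeros(40)].astype(int)
        scores = np.r_[np.ones(38), np.zeros(2), np.ones(6), np.zeros(34)]
        assert roc_auc(scores, labels).auc == pytest.approx(0.900, abs=1e-12)

    def test_negated_marker_complements(self, rng):
        scores = rng.standard_normal(60)
        labels = (rng.random(60) < 0.5).astype(int)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_null_simulation_near_half(self, rng):
        scores = rng.standard_normal(2000)
        labels = np.r_[np.ones(1000), np.zeros(1000)].astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)
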