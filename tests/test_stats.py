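import itertools
import math

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist, hypergeom

from comorbmap.stats import (
    bh_fdr, chi_square, cohen_d, cumulative_logit_or, fisher_exact,
    likelihood_ratio_test, mann_whitney, odds_ratio_2x2, welch_t,
)


class TestOddsRatio:
    def test_uniform_table_or_one(self):
        assert odds_ratio_2x2(1, 1, 1, 1).odds_ratio == 1.0

    def test_cross_product(self):
        r = odds_ratio_2x2(36, 20, 10, 26)
        assert r.odds_ratio == pytest.approx(36 * 26 / (20 * 10))

    def test_woolf_interval(self):
        r = odds_ratio_2x2(36, 20, 10, 26)
        se = math.sqrt(1 / 36 + 1 / 20 + 1 / 10 + 1 / 26)
        assert math.log(r.ci_high / r.odds_ratio) == pytest.approx(1.959964 * se,
                                                                   rel=1e-5)

    def test_zero_cell_undefined_unless_haldane(self):
        r = odds_ratio_2x2(6, 44, 0, 36)
        assert not r.defined
        r2 = odds_ratio_2x2(6, 44, 0, 36, haldane=True)
        assert r2.odds_ratio == pytest.approx(
            (6.5 * 36.5) / (44.5 * 0.5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(-1, 2, 3, 4)

    def test_logistic_mle_equivalence_random_tables(self):
        """For 2x2 tables the cumulative-logit (= binary logistic) MLE
        equals the cross-product ratio to 1e-6."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            a, b, c, d = rng.integers(3, 40, size=4)
            y = np.repeat([1, 0, 1, 0], [a, b, c, d])
            x = np.repeat([1, 1, 0, 0], [a, b, c, d])
            res = cumulative_logit_or(y, x)
            assert res.statistic == pytest.approx(a * d / (b * c), abs=1e-6)


class TestCumulativeLogit:
    def test_balanced_outcome_or_one(self):
        y = np.tile([0, 1, 2], 20)
        x = np.repeat([0.0, 1.0], 30)
        res = cumulative_logit_or(y, x)
        assert res.statistic == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery(self):
        """Proportional-odds data with true common OR 3 is recovered."""
        rng = np.random.default_rng(30)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        beta = math.log(3.0)
        th = [-0.5, 0.8]
        u = rng.random(n)
        p0 = expit(th[0] - beta * x)
        p1 = expit(th[1] - beta * x)
        y = np.where(u < p0, 0, np.where(u < p1, 1, 2))
        res = cumulative_logit_or(y, x)
        assert res.statistic == pytest.approx(3.0, abs=0.3)

    def test_matches_statsmodels(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(31)
        x = rng.integers(0, 2, 300).astype(float)
        y = np.clip(rng.integers(0, 3, 300) + (x * rng.random(300) > 0.6), 0, 2)
        mine = cumulative_logit_or(y, x)
        sm = OrderedModel(y, x[:, None], distr="logit").fit(disp=0)
        assert mine.statistic == pytest.approx(math.exp(sm.params[0]), rel=1e-4)

    def test_separation_reported(self):
        y = np.repeat([0, 2], 20)
        x = np.repeat([0.0, 1.0], 20)
        res = cumulative_logit_or(y, x)
        assert res.statistic != res.statistic  # NaN
        assert "separation" in res.note


class TestContingency:
    def test_independence_gives_zero_g(self):
        res = likelihood_ratio_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_g_matches_direct_formula(self):
        """G = 2 sum O ln(O/E) with E from the margins."""
        obs = np.array([[36.0, 20.0], [10.0, 26.0]])
        row, col = obs.sum(1), obs.sum(0)
        exp = np.outer(row, col) / obs.sum()
        g_manual = 2 * np.sum(obs * np.log(obs / exp))
        res = likelihood_ratio_test(obs)
        assert res.statistic == pytest.approx(g_manual, rel=1e-10)
        assert res.p_value == pytest.approx(
            chi2_dist.sf(g_manual, 1), rel=1e-10)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            res = chi_square([[5, 0, 5], [3, 0, 7]])
        assert res.df == 1

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals exhaustive enumeration of tables with
        the same margins (sum of probabilities <= observed's)."""
        for (a, b, c, d) in [(2, 8, 8, 2), (3, 5, 2, 9), (1, 1, 9, 9)]:
            n1, n0 = a + b, c + d
            k = a + c
            p_obs = hypergeom.pmf(a, n1 + n0, k, n1)
            total = 0.0
            for aa in range(max(0, k - n0), min(k, n1) + 1):
                p = hypergeom.pmf(aa, n1 + n0, k, n1)
                if p <= p_obs * (1 + 1e-9):
                    total += p
            assert fisher_exact(a, b, c, d).p_value == pytest.approx(
                total, rel=1e-8)


class TestRankAndT:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohen_d(x, x) == 0.0
        assert welch_t(x, x).statistic == 0.0

    def test_shifted_samples_reject(self):
        rng = np.random.default_rng(40)
        x = rng.normal(0, 1, 300)
        y = x + 1.0
        assert mann_whitney(y, x).p_value < 1e-3

    def test_u_matches_pair_count_oracle(self):
        """U equals the exhaustive count of (x > y) pairs + half-ties."""
        x = [3.0, 5.0, 7.0, 7.0]
        y = [1.0, 5.0, 6.0]
        u_manual = sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi, yi in itertools.product(x, y))
        assert mann_whitney(x, y).statistic == pytest.approx(u_manual)

    def test_all_tied_degenerate(self):
        with pytest.warns(UserWarning, match="tied"):
            res = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_value == 1.0

    def test_cohen_d_known_value(self):
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 3.0, 5.0])
        assert cohen_d(x, y) == pytest.approx(0.5)


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr([0.01, 0.04, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(50)
        p = rng.random(40)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_sm)

    def test_rejections_match_classical_step_up(self):
        rng = np.random.default_rng(51)
        p = np.concatenate([rng.random(30) * 1e-3, rng.random(30)])
        q = bh_fdr(p)
        alpha, m = 0.05, len(p)
        srt = np.sort(p)
        passing = np.nonzero(srt <= alpha * np.arange(1, m + 1) / m)[0]
        k = passing.max() + 1 if len(passing) else 0
        classical = p <= (srt[k - 1] if k else -1)
        np.testing.assert_array_equal(q <= alpha, classical)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(52)
        p = rng.random(25)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
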