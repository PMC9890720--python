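"""Statistics battery vs independent oracles.

The Freeman-Halton expected values were frozen from R's ``fisher.test`` run
on the same tables; permutation oracles draw tables from the fixed-margin
null with a seeded generator.
"""

import numpy as np
import pytest
from scipy import stats

from immunotopo import statlab
from immunotopo.statlab import ContingencyTable, DegenerateTableError


class TestChiSquare:
    def test_identical_row_proportions_give_zero_statistic(self):
        res = statlab.pearson_chi_square([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degrees_of_freedom_match_shape(self):
        res = statlab.pearson_chi_square([[5, 6, 7], [8, 9, 10], [1, 2, 3]])
        assert res.df == 4

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            statlab.pearson_chi_square([[0, 0], [5, 6]])

    def test_small_expected_count_warns_but_runs(self):
        res = statlab.pearson_chi_square([[13, 4], [32, 1]])
        assert res.warnings and res.p_value == pytest.approx(0.022, abs=5e-4)

    def test_matches_fixed_margin_permutation_oracle(self):
        """Chi-square tail p agrees with a 100k-draw permutation null.

        The oracle draws tables from the fixed-margin (hypergeometric) null.
        That null is discrete, and the chi-square tail corresponds to its
        mid-p (the standard continuity correspondence on a lattice), so the
        comparison uses the Monte-Carlo mid-p on a table large enough for
        the approximation to be in its validity regime.
        """
        observed = np.array([[110, 90], [90, 110]])
        res = statlab.pearson_chi_square(observed)
        rng = np.random.default_rng(42)
        n_draws = 100_000
        row0 = observed.sum(axis=1)[0]
        col = observed.sum(axis=0)
        n = observed.sum()
        a = rng.hypergeometric(col[0], col[1], row0, size=n_draws)
        tables = np.stack(
            [a, row0 - a, col[0] - a, col[1] - (row0 - a)], axis=1
        ).reshape(-1, 2, 2)
        expected = np.outer(observed.sum(1), col) / n
        stats_null = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
        p_ge = (stats_null >= res.statistic - 1e-9).mean()
        p_gt = (stats_null > res.statistic + 1e-9).mean()
        mid_p = (p_ge + p_gt) / 2
        mc_se = np.sqrt(p_ge * (1 - p_ge) / n_draws)
        assert res.p_value == pytest.approx(mid_p, abs=max(4 * mc_se, 0.005))


class TestFisherExact:
    def test_two_by_two_matches_hypergeometric_enumeration(self):
        counts = np.array([[1, 9], [11, 3]])
        res = statlab.fisher_exact(counts)
        # oracle: enumerate the hypergeometric distribution of cell (0,0)
        r0, c0, n = counts.sum(1)[0], counts.sum(0)[0], counts.sum()
        pmf = [stats.hypergeom.pmf(a, n, r0, c0) for a in range(min(r0, c0) + 1)]
        p_obs = stats.hypergeom.pmf(counts[0, 0], n, r0, c0)
        p_exact = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)
        assert res.p_value == pytest.approx(0.00276, abs=5e-6)

    # expected values frozen from R fisher.test on the same 3x2 tables
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([[19, 9], [25, 2], [35, 3]], 0.0215087),
            ([[20, 9], [26, 3], [32, 2]], 0.0207928),
            ([[4, 3], [8, 1], [71, 10]], 0.0986862),
            ([[18, 10], [26, 4], [37, 0]], 7.87011e-05),
            ([[18, 10], [28, 3], [31, 1]], 0.00166982),
        ],
    )
    def test_freeman_halton_matches_r_oracle(self, counts, expected):
        res = statlab.fisher_exact(counts)
        assert res.method == "freeman_halton"
        assert res.p_value == pytest.approx(expected, rel=1e-4)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            statlab.fisher_exact([[0, 0], [3, 4]])

    def test_enumeration_guard(self):
        big = (np.ones((4, 4), dtype=int) * 400).tolist()
        with pytest.raises(ValueError, match="too large"):
            statlab.fisher_exact(big, max_tables=1000)


class TestRankTests:
    def test_spearman_perfect_and_inverse(self):
        x = np.arange(10.0)
        assert statlab.spearman(x, x).statistic == pytest.approx(1.0)
        assert statlab.spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_spearman_matches_midrank_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 10, 30).astype(float)  # ties on purpose
        y = x + rng.normal(0, 2, 30)
        res = statlab.spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(rho, abs=1e-12)

    def test_spearman_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            statlab.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_mann_whitney_identical_groups_p_one(self):
        res = statlab.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_mann_whitney_equals_full_enumeration_small_n(self):
        res = statlab.mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # oracle: enumerate all 6-choose-3 group assignments
        from itertools import combinations

        pooled = np.array([1.0, 2, 3, 4, 5, 6])
        obs_u = res.statistic
        n_extreme = 0
        total = 0
        mean_u = 9 / 2
        for idx in combinations(range(6), 3):
            x = pooled[list(idx)]
            y = np.delete(pooled, list(idx))
            u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
            total += 1
            if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12:
                n_extreme += 1
        assert res.p_value == pytest.approx(n_extreme / total, rel=1e-12)

    def test_kruskal_identical_groups_h_zero(self):
        g = [1.0, 2.0, 3.0]
        res = statlab.kruskal_wallis([g, g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            statlab.kruskal_wallis([[1.0], []])
        with pytest.raises(ValueError):
            statlab.mann_whitney([], [1.0])


class TestDunn:
    def test_two_groups_equals_mann_whitney_z_test(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 8, 15).astype(float)
        y = rng.integers(2, 10, 11).astype(float)
        res = statlab.dunn_posthoc({"a": x, "b": y}, adjustment="none")[0]
        mw = stats.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(mw.pvalue, rel=1e-12)

    def test_holm_adjustment_is_monotone_and_conservative(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(loc, 1, 20) for k, loc in
                  zip("abc", [0.0, 0.8, 2.0])}
        raw = statlab.dunn_posthoc(groups, adjustment="none")
        adj = statlab.dunn_posthoc(groups, adjustment="holm")
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-15


class TestSurvival:
    def test_all_censored_survival_stays_one(self):
        curve = statlab.km_estimate([5.0, 8.0, 12.0], [False, False, False])
        assert np.all(curve.survival == 1.0)
        rmst, se = statlab.restricted_mean(curve, tau=12.0)
        assert rmst == pytest.approx(12.0)
        assert se == pytest.approx(0.0)

    def test_product_limit_by_hand(self):
        curve = statlab.km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert curve.survival_at(2.0) == pytest.approx(1 / 3)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 40)
        curve = statlab.km_estimate(t, np.ones(40, dtype=bool))
        for q in [np.quantile(t, 0.3), np.quantile(t, 0.7)]:
            assert curve.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_restricted_mean_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        rng = np.random.default_rng(3)
        t = rng.exponential(20, 50)
        e = rng.random(50) < 0.7
        curve = statlab.km_estimate(t, e)
        rmst, _ = statlab.restricted_mean(curve, tau=30.0)
        kmf = KaplanMeierFitter().fit(t, e)
        assert rmst == pytest.approx(restricted_mean_survival_time(kmf, t=30.0), rel=1e-9)

    @staticmethod
    def _logrank_stat(times, events, in_a):
        """Hand-rolled two-group log-rank chi-square (independent oracle)."""
        uniq = np.unique(times[events])
        o_minus_e = 0.0
        var = 0.0
        for t in uniq:
            at_risk = times >= t
            n = at_risk.sum()
            n_a = (at_risk & in_a).sum()
            d = (events & (times == t)).sum()
            d_a = (events & (times == t) & in_a).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        return o_minus_e**2 / var

    def test_logrank_matches_permutation_oracle(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, 20).round(1)
        events = rng.random(20) < 0.8
        group = np.array(["a"] * 10 + ["b"] * 10)
        res = statlab.logrank(times, events, group)
        obs = self._logrank_stat(times, events, group == "a")
        assert res.statistic == pytest.approx(obs, rel=1e-9)
        n_draws = 20_000
        stats_null = np.empty(n_draws)
        for i in range(n_draws):
            stats_null[i] = self._logrank_stat(times, events,
                                               rng.permutation(group) == "a")
        p_mc = (stats_null >= obs - 1e-12).mean()
        mc_se = np.sqrt(p_mc * (1 - p_mc) / n_draws)
        assert res.p_value == pytest.approx(p_mc, abs=max(4 * mc_se, 0.015))

    def test_logrank_without_events_rejected(self):
        with pytest.raises(ValueError):
            statlab.logrank([1.0, 2.0], [False, False], ["a", "b"])


class TestContingencyTable:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -1], [2, 3]]))

    def test_chi_square_and_fisher_agree_at_large_n(self):
        base = np.array([[30, 20], [20, 30]])
        rel_diffs = []
        for scale in (1, 4, 16):
            t = base * scale
            p_chi = statlab.pearson_chi_square(t).p_value
            p_f = statlab.fisher_exact(t).p_value
            rel_diffs.append(abs(p_chi - p_f) / p_f)
        assert rel_diffs[2] < rel_diffs[0]
        assert rel_diffs[2] < 0.25
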