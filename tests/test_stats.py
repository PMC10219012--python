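"""Cluster-characterisation statistics against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hingemount.stats import (
    TukeyResult,
    anova_tukey,
    bonwill_balkwill_report,
    chi_square_cramers_v,
    mann_whitney,
    select_discriminative_variables,
    summarize_clusters,
)

# Sex-by-phenotype counts of the three-cluster solution (rows female/male).
SEX_TABLE = [[36, 171, 116], [92, 33, 66]]


def chi2_oracle(table):
    """Hand-rolled Pearson chi-square from the margin products."""
    obs = np.asarray(table, dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return ((obs - exp) ** 2 / exp).sum()


class TestChiSquareCramersV:
    def test_sex_by_cluster_association(self):
        res = chi_square_cramers_v(SEX_TABLE)
        assert res.df == 2
        assert res.chi_square == pytest.approx(chi2_oracle(SEX_TABLE), rel=1e-12)
        assert res.cramers_v == pytest.approx(0.4511, abs=5e-4)
        assert res.p_value < 0.001

    def test_proportional_table_has_zero_association(self):
        res = chi_square_cramers_v([[10, 20, 30], [20, 40, 60]])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.cramers_v == pytest.approx(0.0, abs=1e-9)

    def test_perfect_association_gives_v_one(self):
        res = chi_square_cramers_v([[10, 0], [0, 10]])
        assert res.cramers_v == pytest.approx(1.0)

    def test_row_and_column_swap_invariance(self):
        t = np.array(SEX_TABLE)
        base = chi_square_cramers_v(t).cramers_v
        assert chi_square_cramers_v(t[::-1]).cramers_v == pytest.approx(base)
        assert chi_square_cramers_v(t[:, ::-1]).cramers_v == pytest.approx(base)
        assert chi_square_cramers_v(t.T).cramers_v == pytest.approx(base)

    def test_small_random_tables_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(1, 40, size=(2, 3))
            res = chi_square_cramers_v(t)
            chi2 = chi2_oracle(t)
            assert res.chi_square == pytest.approx(chi2, rel=1e-12)
            assert res.cramers_v == pytest.approx(math.sqrt(chi2 / t.sum()), rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_cramers_v([[0, 0, 0], [1, 2, 3]])


class TestAnovaTukey:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = anova_tukey([g, g.copy(), g.copy()])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0) for _, _, p in res.pairs)
        assert not res.all_pairs_significant

    def test_two_groups_reduce_to_pooled_t_test(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 14), rng.normal(0.8, 1, 9)
        res = anova_tukey([a, b])
        t_p = sps.ttest_ind(a, b).pvalue
        assert res.pairs[0][2] == pytest.approx(t_p, rel=1e-6)
        assert res.anova_p == pytest.approx(t_p, rel=1e-9)  # F = t^2 identity

    def test_widely_separated_groups_all_significant(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1.0, 30) for m in (0.0, 10.0, 20.0)]
        res = anova_tukey(groups)
        assert res.all_pairs_significant
        assert res.anova_p < 1e-10

    def test_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 2.0, 20) for m in (0.0, 0.8, 1.6)]
        res = anova_tukey(groups)
        for (i, j), _, p_adj in res.pairs:
            p_raw = sps.ttest_ind(groups[i], groups[j]).pvalue
            assert p_adj >= p_raw - 1e-12

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([np.ones(5), np.ones(5) * 2.0])


class TestSelectionRule:
    @staticmethod
    def _result(p12, p13, p23):
        return TukeyResult(
            f_statistic=1.0,
            anova_p=0.5,
            pairs=[((0, 1), 0.0, p12), ((0, 2), 0.0, p13), ((1, 2), 0.0, p23)],
            all_pairs_significant=max(p12, p13, p23) < 0.05,
        )

    def test_two_of_three_pairs_excluded(self):
        kept, excluded = select_discriminative_variables(
            {"v": self._result(0.01, 0.01, 0.3)}
        )
        assert kept == [] and excluded == ["v"]

    def test_all_pairs_kept_and_all_null_dropped(self):
        res = {
            "good": self._result(0.001, 0.02, 0.04),
            "null": self._result(1.0, 1.0, 1.0),
        }
        kept, excluded = select_discriminative_variables(res)
        assert kept == ["good"] and excluded == ["null"]

    def test_nine_of_twentytwo_structure(self):
        """Nine all-pairs-separated + thirteen partially separated -> 9 kept."""
        rng = np.random.default_rng(6)
        results = {}
        for i in range(9):
            g = [rng.normal(m, 1.0, 60) for m in (0.0, 2.0, 4.0)]
            results[f"disc{i}"] = anova_tukey(g)
        for i in range(13):
            g = [rng.normal(m, 1.0, 60) for m in (0.0, 0.0, 3.0)]
            results[f"overlap{i}"] = anova_tukey(g)
        kept, excluded = select_discriminative_variables(results)
        assert sorted(kept) == sorted(f"disc{i}" for i in range(9))
        assert len(excluded) == 13


def mann_whitney_exact_p(a, b):
    """Exhaustive-permutation two-sided p for the Mann-Whitney U."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mu = n1 * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.u == 0.0

    def test_identical_groups_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, list(x))
        assert res.u == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value > 0.9

    def test_constant_data_p_one(self):
        res = mann_whitney([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.p_value == 1.0 and res.z == 0.0

    def test_approximation_close_to_exact_permutation(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
            res = mann_whitney(a, b)
            assert abs(res.p_value - mann_whitney_exact_p(a, b)) < 0.02

    def test_matches_scipy_asymptotic_with_ties(self):
        a = [1.0, 2.0, 2.0, 3.0, 5.0, 7.0, 7.0, 9.0]
        b = [2.0, 4.0, 4.0, 6.0, 7.0, 8.0, 10.0]
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
        assert res.u == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestSummaries:
    def test_small_cluster_moments(self):
        df = pd.DataFrame({"alpha_deg": [1.0, 3.0, 10.0]})
        s = summarize_clusters(df, np.array([0, 0, 1]), ["alpha_deg"])
        row = s.variables.loc[(0, "alpha_deg")]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(math.sqrt(2))

    def test_single_cluster_matches_global_stats(self, default_cohort):
        s = summarize_clusters(
            default_cohort, np.zeros(len(default_cohort), dtype=int), ["axh_mm"]
        )
        row = s.variables.loc[(0, "axh_mm")]
        assert row["mean"] == pytest.approx(default_cohort["axh_mm"].mean())
        assert row["sd"] == pytest.approx(default_cohort["axh_mm"].std(ddof=1))
        assert s.sex_counts.loc[0].sum() == len(default_cohort)

    def test_empty_cluster_rejected(self):
        df = pd.DataFrame({"alpha_deg": [1.0]})
        with pytest.raises(ValueError, match="length"):
            summarize_clusters(df, np.array([0, 1]), ["alpha_deg"])

    def test_generator_moments_recovered_within_se(self, default_cohort):
        """Monte-Carlo check: per-cluster summaries match the mixture spec."""
        from hingemount.synthetic import default_generator_spec

        spec = default_generator_spec()
        codes = {c.name: i for i, c in enumerate(spec.clusters)}
        assignments = default_cohort["true_cluster"].map(codes).to_numpy()
        s = summarize_clusters(default_cohort, assignments, ["alpha_deg", "axv_mm", "axh_mm"])
        for i, cl in enumerate(spec.clusters):
            for var in ("alpha_deg", "axv_mm", "axh_mm"):
                row = s.variables.loc[(i, var)]
                se = cl.mounting[var].sd / math.sqrt(cl.n)
                assert abs(row["mean"] - cl.mounting[var].mean) < 4 * se


class TestBonwillBalkwillReport:
    def test_cluster_means_and_flags(self):
        rng = np.random.default_rng(10)
        # two clusters: one near the balanced means, one clearly below range
        ie = np.concatenate([rng.normal(105.3, 5.7, 100), rng.normal(92.1, 5.3, 100)])
        bk = np.concatenate([rng.normal(20.1, 2.4, 100), rng.normal(16.8, 2.4, 100)])
        df = pd.DataFrame({"ie_ax_mm": ie, "balkwill_deg": bk})
        rep = bonwill_balkwill_report(df, np.repeat([0, 1], 100), {0: "balanced", 1: "vertical_II"})
        bal = rep.loc[rep.cluster == 0].iloc[0]
        vert = rep.loc[rep.cluster == 1].iloc[0]
        assert bal["balkwill_flag"] == "within"
        assert vert["balkwill_flag"] == "below"
        assert bal["ie_ax_mean"] == pytest.approx(105.3, abs=2.0)
        assert vert["ie_ax_dev_from_norm"] < -5.0

    def test_empty_report(self):
        rep = bonwill_balkwill_report(
            pd.DataFrame(columns=["ie_ax_mm", "balkwill_deg"]), np.array([])
        )
        assert len(rep) == 0
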