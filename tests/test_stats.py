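"""Group statistics: z-scoring, ANOVA, Tukey-Kramer, differential screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stromatex.stats import anova_oneway, differential_screen, tukey_kramer, zscore_features


def anova_by_sums_of_squares(groups):
    """Hand sums-of-squares oracle: F = (SSB/(k-1)) / (SSW/(N-k))."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    k, n = len(groups), len(all_vals)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestZscore:
    def test_simple_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, excluded = zscore_features(df)
        assert excluded == []
        assert z["a"].mean() == pytest.approx(0.0)
        assert z["a"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_feature_excluded(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        z, excluded = zscore_features(df)
        assert excluded == ["c"]
        assert list(z.columns) == ["a"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        z1, _ = zscore_features(df)
        z2, _ = zscore_features(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert f == 0.0
        assert p == 1.0

    def test_separated_groups_p_tends_to_zero(self):
        prev = 1.0
        for eps in (1.0, 0.1, 0.01):
            rng = np.random.default_rng(0)
            g1 = rng.normal(0, eps, 20)
            g2 = rng.normal(1, eps, 20)
            _, p = anova_oneway([g1, g2])
            assert p <= prev
            prev = p
        assert prev < 1e-10

    def test_three_group_worked_example_matches_ss_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([6.0, 7, 8])]
        f, p = anova_oneway(groups)
        assert f == pytest.approx(anova_by_sums_of_squares(groups))
        assert f == pytest.approx(21.0)
        assert p == pytest.approx(sps.f.sf(21.0, 2, 6))

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0]), np.array([2.0, 3.0])])

    def test_f_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(i, 1, 10) for i in range(3)]
        f1, p1 = anova_oneway(groups)
        f2, p2 = anova_oneway([3.5 * g - 7.0 for g in groups])
        assert f1 == pytest.approx(f2)
        assert p1 == pytest.approx(p2)


class TestTukeyKramer:
    def test_identical_groups_nothing_significant(self):
        g = np.array([1.0, 2.0, 3.0, 2.5])
        res = tukey_kramer([g, g + 0.0, g.copy()])
        assert not any(r["significant"] for r in res.values())

    def test_worked_three_group_example(self):
        groups = [
            np.zeros(5),
            np.array([0.1, -0.1, 0.0, 0.05, -0.05]),
            np.array([10.0, 10.1, 9.9, 10.0, 10.05]),
        ]
        res = tukey_kramer(groups, alpha=0.05)
        assert not res[(0, 1)]["significant"]
        assert res[(0, 2)]["significant"]
        assert res[(1, 2)]["significant"]

    def test_flags_match_statsmodels(self):
        """Independent cross-check against statsmodels' Tukey HSD."""
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 8), rng.normal(0.5, 1, 12), rng.normal(2.0, 1, 6)]
        mine = tukey_kramer(groups, alpha=0.05)
        data = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], [8, 12, 6])
        sm = statsmodels.pairwise_tukeyhsd(data, labels, alpha=0.05)
        sm_flags = list(sm.reject)
        my_flags = [mine[(0, 1)]["significant"], mine[(0, 2)]["significant"], mine[(1, 2)]["significant"]]
        assert my_flags == sm_flags

    def test_familywise_error_calibrated_under_null(self):
        """FWER across seeded null simulations within 3 MC SE of alpha."""
        rng = np.random.default_rng(2024)
        n_sim, alpha, k, n = 600, 0.05, 3, 8
        rejections = 0
        for _ in range(n_sim):
            groups = [rng.normal(size=n) for _ in range(k)]
            res = tukey_kramer(groups, alpha=alpha)
            rejections += any(r["significant"] for r in res.values())
        fwer = rejections / n_sim
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(fwer - alpha) < 3 * se

    def test_unequal_group_sizes_allowed(self):
        rng = np.random.default_rng(3)
        res = tukey_kramer([rng.normal(size=5), rng.normal(size=20), rng.normal(size=7)])
        assert set(res) == {(0, 1), (0, 2), (1, 2)}


class TestDifferentialScreen:
    @pytest.fixture()
    def null_table(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(40, 30)), columns=[f"f{i}" for i in range(30)])
        groups = np.repeat(["a", "b"], 20)
        return table, groups

    def test_bonferroni_threshold_for_full_panel(self, null_table):
        table, groups = null_table
        wide = pd.concat([table] * 8, axis=1)
        wide.columns = [f"f{i}" for i in range(240)]
        res = differential_screen(wide.iloc[:, :212], groups, alpha0=0.05)
        assert res.m == 212
        assert res.alpha_per_test == pytest.approx(0.05 / 212)
        assert res.alpha_per_test == pytest.approx(2.358e-4, rel=1e-3)

    def test_null_table_rarely_significant(self, null_table):
        table, groups = null_table
        res = differential_screen(table, groups)
        assert len(res.significant_features) == 0

    def test_zscoring_does_not_change_pvalues(self, null_table):
        table, groups = null_table
        a = differential_screen(table, groups, zscore=True)
        b = differential_screen(table * 100 - 3, groups, zscore=False)
        assert np.allclose(a.per_feature["p"], b.per_feature["p"])

    def test_significant_set_shrinks_as_m_grows(self):
        rng = np.random.default_rng(9)
        base = pd.DataFrame(
            {
                "strong": np.concatenate([rng.normal(0, 1, 15), rng.normal(3, 1, 15)]),
                "weak": np.concatenate([rng.normal(0, 1, 15), rng.normal(1.1, 1, 15)]),
            }
        )
        groups = np.repeat(["a", "b"], 15)
        small = differential_screen(base, groups)
        padded = base.copy()
        for i in range(80):
            padded[f"noise{i}"] = rng.normal(size=30)
        large = differential_screen(padded, groups)
        assert set(large.significant_features) <= set(small.significant_features)

    def test_three_group_venn_and_gatekeeping(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame(
            {
                "shifted": np.concatenate(
                    [rng.normal(0, 1, 12), rng.normal(0, 1, 12), rng.normal(5, 1, 12)]
                ),
                "flat": rng.normal(size=36),
            }
        )
        groups = np.repeat(["g1", "g2", "g3"], 12)
        res = differential_screen(table, groups)
        assert res.significant_features == ["shifted"]
        assert set(res.pairwise) == {"shifted"}  # gatekeeping: only significant features
        flags = res.pairwise["shifted"]
        assert flags[("g1", "g3")] and flags[("g2", "g3")] and not flags[("g1", "g2")]
        assert res.venn[("g1", "g3")] == 1 and res.venn[("g1", "g2")] == 0

    def test_pairwise_flags_symmetric_in_pair_order(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 10), rng.normal(4, 1, 10), rng.normal(0, 1, 10)]
        res_fwd = tukey_kramer(groups)
        res_rev = tukey_kramer(groups[::-1])
        # pair (i,j) in forward order corresponds to (k-1-j, k-1-i) reversed
        assert res_fwd[(0, 1)]["significant"] == res_rev[(1, 2)]["significant"]
        assert res_fwd[(0, 2)]["significant"] == res_rev[(0, 2)]["significant"]
        assert res_fwd[(1, 2)]["significant"] == res_rev[(0, 1)]["significant"]
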