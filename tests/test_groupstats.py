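"""Normality, ANOVA, Bonferroni post hoc, Kruskal-Wallis, Pearson."""
import numpy as np
import pytest
from scipy import stats as sst

from kindleeg import (
    anova_from_summary,
    bonferroni_pairwise,
    kruskal_wallis,
    ks_normality,
    one_way_anova,
    pearson_r,
    two_way_anova,
)
from kindleeg.exceptions import DegenerateInputError

from oracles import permutation_pearson_p


class TestNormality:
    def test_null_coverage(self):
        # under the null (normal data) the rejection rate at alpha = 0.05
        # should match the nominal level within Monte-Carlo error (3 sigma
        # of a binomial with p = 0.95 over 400 replicates is ~0.033)
        rng = np.random.default_rng(0)
        kept = sum(ks_normality(rng.standard_normal(1000)).p_value > 0.05 for _ in range(400))
        assert kept / 400 >= 0.917

    def test_uniform_grid_rejected(self):
        sample = np.linspace(0.0, 1.0, 1000)
        assert ks_normality(sample).p_value < 0.05

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            ks_normality([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            ks_normality([3.0] * 10)


class TestOneWayAnova:
    def test_identical_means_zero_f(self):
        res = one_way_anova([[1.0, 2.0, 3.0], [0.0, 2.0, 4.0], [1.5, 2.0, 2.5]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.statistic == pytest.approx(3.0, abs=1e-9)
        assert res.df == (2, 6)

    def test_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        f_res = one_way_anova([a, b])
        t, _ = sst.ttest_ind(a, b)
        assert f_res.statistic == pytest.approx(t**2, rel=1e-9)

    def test_summary_matches_raw(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1.3, n) for m, n in [(0, 7), (0.4, 6), (1.1, 6)]]
        raw = one_way_anova(groups)
        summ = anova_from_summary(
            [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups],
            [g.size for g in groups],
        )
        assert summ.statistic == pytest.approx(raw.statistic, rel=1e-9)
        assert summ.p_value == pytest.approx(raw.p_value, rel=1e-9)
        assert summ.df == raw.df

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(0, 1, 6) for _ in range(3)]
        a = one_way_anova(groups)
        b = one_way_anova([g * 17.0 for g in groups])
        assert b.statistic == pytest.approx(a.statistic, rel=1e-9)

    def test_singleton_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestBonferroni:
    def test_three_groups_three_comparisons(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 6) for m in (0, 1, 2)]
        res = bonferroni_pairwise(groups, labels=["a", "b", "c"])
        assert len(res) == 3
        for r in res:
            assert r.p_value == pytest.approx(min(1.0, r.p_raw * 3), rel=1e-12)

    def test_adjusted_p_capped_at_one(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 10)
        groups = [base, base + 0.01 * rng.normal(size=10), base + 0.01 * rng.normal(size=10)]
        assert any(r.p_value == 1.0 for r in bonferroni_pairwise(groups))

    def test_equal_means_all_insignificant(self):
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 1, 8)
        groups = [np.r_[noise, 1.0], np.r_[noise, 1.0], np.r_[noise, 1.0]]
        for r in bonferroni_pairwise(groups):
            assert r.statistic == pytest.approx(0.0, abs=1e-12)
            assert r.p_value == 1.0


class TestTwoWayAnova:
    @staticmethod
    def _balanced(rng, effect_a=(0.0, 1.0), effect_b=(0.0, 2.0), inter=0.0, noise=1.0, n=5):
        values, fa, fb = [], [], []
        for i, a in enumerate(effect_a):
            for j, b in enumerate(effect_b):
                cell = a + b + inter * i * j + noise * rng.standard_normal(n)
                values.extend(cell)
                fa.extend([f"a{i}"] * n)
                fb.extend([f"b{j}"] * n)
        return np.asarray(values), fa, fb

    def test_additive_noise_free_interaction_zero(self):
        values, fa, fb = [], [], []
        for i, a in enumerate((0.0, 1.0, 2.0)):
            for j, b in enumerate((0.0, 3.0)):
                for rep in range(3):
                    values.append(a + b + 0.1 * rep)  # replicate effect, no a×b term
                    fa.append(f"a{i}")
                    fb.append(f"b{j}")
        res = two_way_anova(values, fa, fb)
        ss_inter = res["interaction"].statistic * res["interaction"].df[0]
        # F = (SS_i/df_i)/MS_e; with additive data SS_interaction = 0 so F = 0
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_single_level_factor_reduces_to_one_way(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1, 6) for m in (0, 0.5, 1.5)]
        values = np.concatenate(groups)
        fa = ["g0"] * 6 + ["g1"] * 6 + ["g2"] * 6
        fb = ["only"] * 18
        res = two_way_anova(values, fa, fb)
        ref = one_way_anova(groups)
        assert res["group"].statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert res["phase"] is None and res["interaction"] is None

    def test_balanced_decomposition_identity(self):
        rng = np.random.default_rng(8)
        values, fa, fb = self._balanced(rng, inter=0.7)
        res = two_way_anova(values, fa, fb)
        # reconstruct sums of squares from F, df and the residual MS
        n = len(values)
        df_err = res["group"].df[1]
        # residual SS from total minus effects, using the model identity
        import pandas as pd
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        df = pd.DataFrame({"y": values, "a": fa, "b": fb})
        table = anova_lm(ols("y ~ C(a) * C(b)", data=df).fit(), typ=2)
        ss_total = float(np.sum((values - np.mean(values)) ** 2))
        assert table["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_empty_cell_flagged(self):
        values = [1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 4.0, 5.0, 3.5, 4.5]
        fa = ["a0"] * 4 + ["a1"] * 4 + ["a0", "a1"]
        fb = ["b0", "b0", "b1", "b1"] * 2 + ["b2", "b2"]
        fa2 = ["a0"] * 5 + ["a1"] * 5
        fb2 = ["b0", "b0", "b1", "b1", "b2", "b0", "b0", "b1", "b1", "b1"]  # a1×b2 empty
        res = two_way_anova(values, fa2, fb2)
        assert res["interaction"].flag == "missing-cell"
        assert np.isfinite(res["group"].statistic)


class TestKruskalWallis:
    def test_complete_ties_zero(self):
        res = kruskal_wallis([[2.0, 2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0

    def test_hand_computed_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.8571, abs=1e-3)
        assert res.df == 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        a, b, c = rng.normal(0, 1, 7), rng.normal(1, 1, 6), rng.normal(2, 1, 6)
        base = kruskal_wallis([a, b, c])
        transformed = kruskal_wallis([np.exp(a), np.exp(b), np.exp(c)])
        assert transformed.statistic == pytest.approx(base.statistic, rel=1e-12)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        res = pearson_r([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(0.98198, abs=1e-4)

    def test_affine_invariance(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = pearson_r(x, y)
        b = pearson_r(3 * x - 7, -2 * y + 4)
        assert abs(b.r) == pytest.approx(abs(a.r), rel=1e-12)

    def test_p_close_to_permutation_null(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = pearson_r(x, y)
        p_perm = permutation_pearson_p(x, y, n_perm=10_000, seed=0)
        assert res.p_value == pytest.approx(p_perm, abs=0.03)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 2.0], [1.0, 2.0])
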