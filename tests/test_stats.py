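from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fearscope import stats as fs
from fearscope.core import (
    DegenerateInputError,
    InvalidArgumentError,
    NoSolutionError,
)


class TestChiSquare:
    def test_identical_proportions_zero(self):
        res = fs.chi_square_independence([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_2x3_matches_hand_formula(self):
        table = np.array([[5, 10, 15], [15, 10, 5]], dtype=float)
        res = fs.chi_square_independence(table)
        # brute-force sum((O-E)^2/E) with E from the marginals
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(by_hand)
        assert res.df == 2

    def test_zero_marginal(self):
        with pytest.raises(DegenerateInputError):
            fs.chi_square_independence([[0, 0], [5, 5]])

    def test_exhaustive_small_tables(self, rng):
        for _ in range(10):
            table = rng.integers(1, 12, size=(2, 2)).astype(float)
            res = fs.chi_square_independence(table)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            e = row * col / table.sum()
            assert res.statistic == pytest.approx(((table - e) ** 2 / e).sum())
            assert res.p_value == pytest.approx(sps.chi2.sf(res.statistic, 1))


def kw_by_hand(groups):
    """Tie-corrected Kruskal-Wallis H from first principles."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (ranks[bounds[i] : bounds[i + 1]].mean() - (n + 1) / 2) ** 2
        for i, g in enumerate(groups)
    )
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestKruskalWallisAndDunn:
    def test_identical_groups_zero(self):
        res = fs.kruskal_wallis([1, 2, 3, 7], [3, 2, 1, 7])
        assert res.statistic == pytest.approx(0.0)

    def test_all_tied_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fs.kruskal_wallis([1, 1], [1, 1, 1])

    def test_three_group_rank_arithmetic(self):
        groups = ([1.0, 3.0, 5.0], [2.0, 4.0, 9.0], [6.0, 7.0, 8.0])
        res = fs.kruskal_wallis(*groups)
        assert res.statistic == pytest.approx(kw_by_hand(groups))

    def test_brute_force_with_ties(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 5, rng.integers(3, 7)).astype(float)
                      for _ in range(3)]
            if np.unique(np.concatenate(groups)).size < 2:
                continue
            res = fs.kruskal_wallis(*groups)
            assert res.statistic == pytest.approx(kw_by_hand(groups))

    def test_two_group_direction_consistent_with_mannwhitney(self):
        # KW reduces to a monotone function of the two-sample rank test: the
        # significance calls agree and the p-values track each other
        for seed in range(20):
            r = np.random.default_rng(seed)
            shift = 0.0 if seed % 2 else 1.2
            x, y = r.normal(0, 1, 12), r.normal(shift, 1, 12)
            kw = fs.kruskal_wallis(x, y)
            u = fs.mann_whitney(x, y)
            # the two p-values come from different approximations (chi2 vs
            # exact), so compare on the log scale rather than at a hard cut
            assert abs(np.log10(kw.p_value) - np.log10(u.p_value)) < 0.5

    def test_dunn_mean_rank_difference(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        out = fs.dunns_posthoc(groups)
        first = out.iloc[0]
        assert first["mean_rank_diff"] == pytest.approx(2.0 - 5.0)
        # hand-computed z for untied data: se = sqrt(N(N+1)/12 * 2/3)
        se = np.sqrt(9 * 10 / 12 * (2 / 3))
        assert first["z"] == pytest.approx(-3.0 / se)
        assert first["p_adjusted"] == pytest.approx(min(first["p_raw"] * 3, 1.0))

    def test_dunn_comparison_subset_bonferroni(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        subset = fs.dunns_posthoc(groups, comparisons=[(0, 2)])
        full = fs.dunns_posthoc(groups)
        row_full = full[(full.group_i == 0) & (full.group_j == 2)].iloc[0]
        assert subset.iloc[0]["p_raw"] == pytest.approx(row_full["p_raw"])
        assert subset.iloc[0]["p_adjusted"] == pytest.approx(
            min(row_full["p_raw"], 1.0)
        )


class TestMannWhitneyWilcoxon:
    def test_identical_samples_u_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = fs.mann_whitney(x, x)
        assert res.extras["U1"] + res.extras["U2"] == 16
        assert res.statistic == 8.0  # n1*n2/2

    def test_complete_separation_exact_p(self):
        # n1=n2=3, all x < y: U=0; 2 of the C(6,3)=20 arrangements are as or
        # more extreme -> exact two-tailed p = 0.1
        res = fs.mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.statistic == 0.0
        assert res.extras["exact"]
        assert res.p_value == pytest.approx(0.1)

    def test_exact_matches_enumeration(self, rng):
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.5, 1, 6)
        res = fs.mann_whitney(x, y)
        # enumerate all group assignments of the pooled sample
        pooled = np.concatenate([x, y])
        n1 = x.size
        count = 0
        total = 0
        u_obs = res.statistic
        for idx in combinations(range(pooled.size), n1):
            xa = pooled[list(idx)]
            ya = np.delete(pooled, list(idx))
            u1 = sum((xi > ya).sum() for xi in xa)
            u = min(u1, n1 * ya.size - u1)
            total += 1
            if u <= u_obs + 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total)

    def test_swap_symmetry(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        a, b = fs.mann_whitney(x, y), fs.mann_whitney(y, x)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_empty_input(self):
        with pytest.raises(InvalidArgumentError):
            fs.mann_whitney([], [1.0])

    def test_wilcoxon_all_zero_convention(self):
        res = fs.wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.extras["degenerate"]

    def test_wilcoxon_matches_scipy(self, rng):
        d = rng.normal(0.5, 1, 12)
        res = fs.wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


def balanced_rm_frame(rng, n_per_group=8, n_within=4, group_shift=0.0,
                      within_shift=0.0):
    rows = []
    for gi, g in enumerate(("ctrl", "arch")):
        for s in range(n_per_group):
            base = rng.normal(gi * group_shift, 1.0)
            for m in range(n_within):
                rows.append(
                    {"subject": f"{g}{s}", "group": g, "epoch": m,
                     "value": base + within_shift * m + rng.normal(0, 0.5)}
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_f_equals_t_squared_between(self, rng):
        df = balanced_rm_frame(rng, n_per_group=6, n_within=2, group_shift=1.0)
        res = fs.rm_anova_two_way(df)
        means = df.groupby(["subject", "group"], observed=True)["value"].mean()
        means = means.reset_index()
        t = fs.t_test_unpaired(
            means.loc[means.group == "ctrl", "value"],
            means.loc[means.group == "arch", "value"],
        )
        assert res["between"].statistic == pytest.approx(t.statistic**2)
        assert res["between"].df == (1, 10)

    def test_f_within_equals_pooled_paired_t_squared(self, rng):
        df = balanced_rm_frame(rng, n_per_group=7, n_within=2, within_shift=0.8)
        res = fs.rm_anova_two_way(df)
        wide = df.pivot_table(index=["subject", "group"], columns="epoch",
                              values="value").reset_index()
        d = wide[1] - wide[0]
        # group-centred pooled variance of the within-differences
        centred = d - d.groupby(wide["group"], observed=True).transform("mean")
        s2 = (centred**2).sum() / (len(d) - 2)
        t2 = len(d) * d.mean() ** 2 / s2
        assert res["within"].statistic == pytest.approx(t2)

    def test_null_simulation_f_near_one(self):
        rng = np.random.default_rng(0)
        fvals = [
            fs.rm_anova_two_way(balanced_rm_frame(rng))["between"].statistic
            for _ in range(100)
        ]
        # E[F] = df2/(df2-2) = 14/12 for df (1, 14)
        assert np.mean(fvals) == pytest.approx(14 / 12, rel=0.25)

    def test_f_monotone_in_effect_size(self):
        rng = np.random.default_rng(1)
        fvals = []
        for shift in (0.0, 0.7, 1.5, 3.0):
            vals = [
                fs.rm_anova_two_way(
                    balanced_rm_frame(np.random.default_rng(100 + k),
                                      group_shift=shift)
                )["between"].statistic
                for k in range(20)
            ]
            fvals.append(np.mean(vals))
        assert fvals == sorted(fvals)

    def test_unbalanced_rejected(self, rng):
        df = balanced_rm_frame(rng)
        with pytest.raises(InvalidArgumentError):
            fs.rm_anova_two_way(df.iloc[:-1])

    def test_sidak(self):
        assert fs.sidak_adjust(0.02, 4) == pytest.approx(1 - 0.98**4)
        with pytest.raises(InvalidArgumentError):
            fs.sidak_adjust(1.2, 3)


class TestSummaryReconstruction:
    def test_printed_ci_lower_bound(self):
        lo, hi = fs.ci_from_mean_sem(8.8, 1.6, 12)
        assert lo == pytest.approx(5.28, abs=0.01)

    def test_t_from_printed_cis(self):
        t, df = fs.t_from_cis((1.687, 2.764), 11, (3.128, 4.719), 12)
        assert abs(t) == pytest.approx(3.833, abs=0.01)
        assert df == 21

    def test_identical_cis_zero_t(self):
        t, df = fs.t_from_cis((1.0, 2.0), 10, (1.0, 2.0), 10)
        assert t == pytest.approx(0.0)

    def test_roundtrip_mean_sem(self, rng):
        mean, sem, n = 3.7, 0.42, 15
        lo, hi = fs.ci_from_mean_sem(mean, sem, n)
        assert 0.5 * (lo + hi) == pytest.approx(mean)
        halfwidth = 0.5 * (hi - lo)
        assert halfwidth / sps.t.ppf(0.975, n - 1) == pytest.approx(sem)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            fs.ci_from_mean_sem(1.0, -0.1, 10)
        with pytest.raises(InvalidArgumentError):
            fs.t_from_cis((2.0, 1.0), 10, (1.0, 2.0), 10)


class TestPower:
    def spec(self, **kw):
        base = dict(effect_size_f=0.667, alpha=0.05, target_power=0.85,
                    groups=2, measures=4, corr=0.5)
        base.update(kw)
        return fs.PowerSpec(**base)

    def test_published_inputs_give_n16(self):
        res = fs.rm_anova_power(self.spec())
        assert res.n_total == 16
        assert res.f_crit == pytest.approx(4.6, abs=0.05)
        assert res.power >= 0.85

    def test_minimality(self):
        res = fs.rm_anova_power(self.spec())
        smaller = fs.rm_anova_power_at_n(self.spec(), res.n_total - 2)
        assert smaller.power < 0.85

    def test_power_monotone_in_n_and_f(self):
        p1 = fs.rm_anova_power_at_n(self.spec(), 10).power
        p2 = fs.rm_anova_power_at_n(self.spec(), 20).power
        assert p2 > p1
        weak = fs.rm_anova_power_at_n(self.spec(effect_size_f=0.3), 16).power
        strong = fs.rm_anova_power_at_n(self.spec(effect_size_f=0.9), 16).power
        assert strong > weak

    def test_power_decreasing_in_corr(self):
        lo = fs.rm_anova_power_at_n(self.spec(corr=0.0), 16).power
        hi = fs.rm_anova_power_at_n(self.spec(corr=0.9), 16).power
        assert hi < lo

    def test_unreachable_power(self):
        with pytest.raises(NoSolutionError):
            fs.rm_anova_power(self.spec(effect_size_f=1e-6), max_n=100)

    def test_invalid_spec(self):
        with pytest.raises(InvalidArgumentError):
            fs.rm_anova_power(self.spec(alpha=1.5))
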