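"""Statistical battery: nonparametric multi-group tests, t tests,
mixed repeated-measures ANOVA, summary-statistic reconstruction and the
noncentral-F power computation for a repeated-measures design.

Conventions: all tests are two-tailed; the Mann-Whitney U is reported as
``min(U1, U2)`` with an exact p-value for small untied samples; Dunn's
post-hoc z tests are Bonferroni-adjusted over the requested comparisons
only; the mixed ANOVA is the classical pooled-error form without sphericity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from fearscope.core import (
    DegenerateInputError,
    InvalidArgumentError,
    NoSolutionError,
)

EXACT_U_MAX_N = 25


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: Optional[object] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
        }
        d.update(self.extras)
        return d


# ---------------------------------------------------------------------------
# contingency / rank tests


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise InvalidArgumentError("need a table with >= 2 rows and columns")
    if (table < 0).any():
        raise InvalidArgumentError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero marginal in contingency table")
    stat, p, dof, expected = sps.chi2_contingency(table, correction=False)
    return TestResult(
        name="chi_square",
        statistic=float(stat),
        p_value=float(p),
        df=int(dof),
        extras={"expected": expected},
    )


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups."""
    if len(groups) < 2:
        raise InvalidArgumentError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise InvalidArgumentError("groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise DegenerateInputError("all values tied across all groups")
    stat, p = sps.kruskal(*arrays)
    return TestResult(
        name="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        df=len(arrays) - 1,
    )


def dunns_posthoc(
    groups: Sequence[Sequence[float]],
    comparisons: Optional[Sequence[tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with Bonferroni adjustment.

    ``comparisons`` selects group-index pairs (default: all pairs); the
    Bonferroni factor is the number of *requested* comparisons.  Returns one
    row per comparison with the mean-rank difference, z, raw and adjusted p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if comparisons is None:
        comparisons = [
            (i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))
        ]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(comparisons)
    rows = []
    for i, j in comparisons:
        diff = mean_ranks[i] - mean_ranks[j]
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = diff / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "group_i": i,
                "group_j": j,
                "mean_rank_diff": diff,
                "z": z,
                "p_raw": p,
                "p_adjusted": min(p * k, 1.0) if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U test; U reported as ``min(U1, U2)``.

    Exact p for samples of at most 25 without ties, normal approximation
    (tie-corrected, continuity-corrected) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (max(x.size, y.size) <= EXACT_U_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    return TestResult(
        name="mann_whitney",
        statistic=min(u1, u2),
        p_value=float(res.pvalue),
        df=None,
        extras={"U1": u1, "U2": u2, "exact": exact},
    )


def wilcoxon_signed_rank(differences: Sequence[float]) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    All-zero differences are reported as W=0, p=1 with a ``degenerate`` flag
    rather than raising.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise InvalidArgumentError("empty sample")
    if np.all(d == 0):
        return TestResult(
            name="wilcoxon",
            statistic=0.0,
            p_value=1.0,
            df=None,
            extras={"degenerate": True},
        )
    res = sps.wilcoxon(d, alternative="two-sided")
    return TestResult(
        name="wilcoxon",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=None,
        extras={"degenerate": False},
    )


# ---------------------------------------------------------------------------
# t tests


def t_test_unpaired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidArgumentError("need >= 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(
        name="t_unpaired",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=x.size + y.size - 2,
    )


def t_test_paired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InvalidArgumentError("paired samples must have equal size >= 2")
    res = sps.ttest_rel(x, y)
    return TestResult(
        name="t_paired",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=x.size - 1,
    )


def t_test_one_sample(x: Sequence[float], popmean: float = 0.0) -> TestResult:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("need >= 2 observations")
    res = sps.ttest_1samp(x, popmean)
    return TestResult(
        name="t_one_sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=x.size - 1,
    )


# ---------------------------------------------------------------------------
# mixed (between x within) repeated-measures ANOVA


def rm_anova_two_way(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str = "group",
    within: str = "epoch",
) -> dict[str, TestResult]:
    """Classical balanced mixed ANOVA (between-group x repeated measure).

    Requires a balanced layout: every subject appears once per within level
    and group sizes are equal.  Returns F tests for the between factor
    (against the subjects-within-groups error), the within factor and the
    interaction (against the pooled within-subjects error).  No sphericity
    correction is applied.
    """
    for col in (dv, subject, between, within):
        if col not in data.columns:
            raise InvalidArgumentError(f"column {col!r} missing")
    groups = sorted(data[between].unique())
    withins = sorted(data[within].unique())
    a, b = len(groups), len(withins)
    if a < 2 or b < 2:
        raise InvalidArgumentError("need >= 2 levels of each factor")

    cell = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean", observed=True
    )
    subj_group = data.groupby(subject, observed=True)[between].first()
    sizes = subj_group.value_counts()
    if cell.isna().any().any() or sizes.nunique() != 1 or len(sizes) != a:
        raise InvalidArgumentError(
            "unbalanced design: need equal group sizes and complete subjects"
        )
    counts = data.groupby([subject, within], observed=True)[dv].count()
    if (counts != 1).any():
        raise InvalidArgumentError("each subject must have one value per level")

    s = int(sizes.iloc[0])  # subjects per group
    y = cell.loc[subj_group.index].to_numpy()  # subjects x within
    g = subj_group.to_numpy()
    grand = y.mean()

    group_means = np.array([y[g == grp].mean() for grp in groups])
    subj_means = y.mean(axis=1)
    within_means = y.mean(axis=0)
    cell_means = np.array([y[g == grp].mean(axis=0) for grp in groups])  # a x b

    ss_between = s * b * np.sum((group_means - grand) ** 2)
    ss_subj = b * np.sum(
        (subj_means - np.array([group_means[groups.index(gi)] for gi in g])) ** 2
    )
    ss_within = a * s * np.sum((within_means - grand) ** 2)
    ss_inter = s * np.sum(
        (cell_means - group_means[:, None] - within_means[None, :] + grand) ** 2
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_between - ss_subj - ss_within - ss_inter

    df_between, df_subj = a - 1, a * (s - 1)
    df_within, df_inter = b - 1, (a - 1) * (b - 1)
    df_err = a * (s - 1) * (b - 1)

    def f_test(label: str, ss_num, df_num, ss_den, df_den) -> TestResult:
        ms_num, ms_den = ss_num / df_num, ss_den / df_den
        f = ms_num / ms_den if ms_den > 0 else np.nan
        p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else np.nan
        return TestResult(
            name=f"rm_anova_{label}",
            statistic=float(f),
            p_value=p,
            df=(df_num, df_den),
            extras={"ss": float(ss_num)},
        )

    return {
        "between": f_test("between", ss_between, df_between, ss_subj, df_subj),
        "within": f_test("within", ss_within, df_within, ss_err, df_err),
        "interaction": f_test("interaction", ss_inter, df_inter, ss_err, df_err),
    }


def sidak_adjust(p: float, n_comparisons: int) -> float:
    """Sidak family-wise adjustment ``1 - (1 - p)^k``."""
    if not 0.0 <= p <= 1.0 or n_comparisons < 1:
        raise InvalidArgumentError("need p in [0,1] and k >= 1")
    return float(1.0 - (1.0 - p) ** n_comparisons)


# ---------------------------------------------------------------------------
# summary-statistic reconstruction


def ci_from_mean_sem(mean: float, sem: float, n: int) -> tuple[float, float]:
    """95% confidence interval ``mean +/- t(0.975, n-1) * sem``."""
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    if sem <= 0:
        raise InvalidArgumentError("sem must be positive")
    tcrit = sps.t.ppf(0.975, n - 1)
    return (mean - tcrit * sem, mean + tcrit * sem)


def t_from_cis(
    ci1: tuple[float, float], n1: int, ci2: tuple[float, float], n2: int
) -> tuple[float, int]:
    """Pooled unpaired t statistic reconstructed from two printed 95% CIs.

    Means are the CI midpoints; SEMs are halfwidth / t(0.975, n-1); the
    returned statistic is the pooled-variance two-sample t with
    ``df = n1 + n2 - 2``.
    """
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("need n >= 2 in both groups")
    out = []
    for (lo, hi), n in ((ci1, n1), (ci2, n2)):
        width = hi - lo
        if width <= 0:
            raise InvalidArgumentError("CI width must be positive")
        mean = 0.5 * (lo + hi)
        sem = 0.5 * width / sps.t.ppf(0.975, n - 1)
        out.append((mean, sem * np.sqrt(n)))  # (mean, sd)
    (m1, sd1), (m2, sd2) = out
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float((m1 - m2) / se), df


# ---------------------------------------------------------------------------
# power analysis for the repeated-measures design


@dataclass
class PowerSpec:
    """Inputs of the between-subjects RM-ANOVA sample-size computation."""

    effect_size_f: float
    alpha: float = 0.05
    target_power: float = 0.85
    groups: int = 2
    measures: int = 4
    corr: float = 0.5
    equal_groups: bool = True

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise InvalidArgumentError("target power must be in (0, 1)")
        if self.measures < 2 or self.groups < 2:
            raise InvalidArgumentError("need >= 2 groups and >= 2 measures")
        if not -1.0 < self.corr < 1.0:
            raise InvalidArgumentError("corr must be in (-1, 1)")
        if self.effect_size_f <= 0:
            raise InvalidArgumentError("effect size must be positive")


@dataclass
class PowerResult:
    n_total: int
    f_crit: float
    power: float
    noncentrality: float
    df: tuple[int, int]


def rm_anova_power_at_n(spec: PowerSpec, n_total: int) -> PowerResult:
    """Power of the between-subjects effect at a given total sample size.

    Noncentrality ``lambda = f^2 * N * m / (1 + (m-1)*rho)`` with ``df =
    (groups-1, N-groups)``; power is the upper tail of the noncentral F
    beyond the central F criterion.
    """
    spec.validate()
    if n_total <= spec.groups:
        raise InvalidArgumentError("n_total must exceed the number of groups")
    m, rho = spec.measures, spec.corr
    lam = spec.effect_size_f**2 * n_total * m / (1.0 + (m - 1) * rho)
    df1, df2 = spec.groups - 1, n_total - spec.groups
    f_crit = float(sps.f.ppf(1.0 - spec.alpha, df1, df2))
    power = float(sps.ncf.sf(f_crit, df1, df2, lam))
    return PowerResult(
        n_total=n_total,
        f_crit=f_crit,
        power=power,
        noncentrality=lam,
        df=(df1, df2),
    )


def rm_anova_power(spec: PowerSpec, max_n: int = 10**6) -> PowerResult:
    """Smallest total N whose between-subjects power reaches the target.

    With ``equal_groups`` set, N is constrained to multiples of the group
    count.  Raises :class:`NoSolutionError` if no N up to ``max_n`` works.
    """
    spec.validate()
    step = spec.groups if spec.equal_groups else 1
    start = 2 * spec.groups if spec.equal_groups else spec.groups + 1
    n = start
    while n <= max_n:
        result = rm_anova_power_at_n(spec, n)
        if result.power >= spec.target_power:
            return result
        n += step
    raise NoSolutionError(f"target power unreachable with N <= {max_n}")
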