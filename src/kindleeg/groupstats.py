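"""Group-level statistics: normality, ANOVA with Bonferroni post hoc,
Kruskal-Wallis, and Pearson correlation.

These mirror the statistical layer of a stage-stratified spectral study:
Kolmogorov-Smirnov normality screening (with Lilliefors correction, since
the normal parameters are estimated from the same sample), one-way ANOVA
across groups with Bonferroni-adjusted pairwise post hoc t-tests on the
pooled within-group mean square, two-way (group × phase) ANOVA with Type-II
sums of squares (the designs are heavily unbalanced), Kruskal-Wallis H with
tie correction, and Pearson correlation between AD duration and band power.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import DegenerateInputError


@dataclass
class StatResult:
    """A named test statistic with degrees of freedom and p-value."""

    test_name: str
    statistic: float
    df: tuple | int
    p_value: float
    group_labels: tuple = ()
    p_raw: float | None = None
    flag: str = ""


@dataclass
class CorrelationResult:
    """Pearson correlation with sample size and two-sided p-value."""

    r: float
    n: int
    p_value: float


def _as_groups(groups):
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise DegenerateInputError("need at least two groups")
    for g in out:
        if g.size < 2:
            raise DegenerateInputError("every group needs at least two observations")
    return out


def ks_normality(sample) -> StatResult:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Uses Lilliefors critical values because mean and SD are fitted to the
    sample itself; the plain KS test against fixed parameters would be
    anti-conservative here.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 3:
        raise DegenerateInputError("normality test requires n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample has no distribution to test")
    d, p = lilliefors(x, dist="norm")
    return StatResult("ks-lilliefors", float(d), int(x.size), float(p))


def anova_from_summary(means, sds, ns) -> StatResult:
    """One-way ANOVA from per-group (mean, SD, n) summary statistics."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if means.size < 2 or np.any(ns < 2):
        raise DegenerateInputError("need >= 2 groups with n >= 2 each")
    k, n_tot = means.size, int(ns.sum())
    grand = float(np.sum(ns * means) / n_tot)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df1, df2 = k - 1, n_tot - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        raise DegenerateInputError("zero within-group variance")
    f = ms_between / ms_within
    p = float(sst.f.sf(f, df1, df2))
    return StatResult("one-way-anova", f, (df1, df2), p)


def one_way_anova(groups, labels=None) -> StatResult:
    """One-way ANOVA: F = MS_between / MS_within, df (k-1, N-k)."""
    gs = _as_groups(groups)
    if all(np.ptp(g) == 0 for g in gs) and len({float(g[0]) for g in gs}) == 1:
        # identical constant groups: F = 0/0; report F = 0 by convention
        return StatResult(
            "one-way-anova", 0.0, (len(gs) - 1, sum(g.size for g in gs) - len(gs)), 1.0,
            group_labels=tuple(labels or ()),
        )
    f, p = sst.f_oneway(*gs)
    df = (len(gs) - 1, sum(g.size for g in gs) - len(gs))
    return StatResult("one-way-anova", float(f), df, float(p), group_labels=tuple(labels or ()))


def bonferroni_pairwise(groups, alpha: float = 0.05, labels=None) -> list[StatResult]:
    """All pairwise t-tests on the omnibus pooled MS, Bonferroni-adjusted.

    The standard error uses the pooled within-group mean square from the
    one-way ANOVA (df = N - k); adjusted p = min(1, raw p × number of
    comparisons).
    """
    gs = _as_groups(groups)
    k = len(gs)
    n_tot = sum(g.size for g in gs)
    labels = list(labels) if labels is not None else list(range(k))
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df_err = n_tot - k
    ms_within = ss_within / df_err
    if ms_within == 0:
        raise DegenerateInputError("zero within-group variance")
    m = k * (k - 1) // 2
    results = []
    for i, j in combinations(range(k), 2):
        gi, gj = gs[i], gs[j]
        se = np.sqrt(ms_within * (1.0 / gi.size + 1.0 / gj.size))
        t = float((gi.mean() - gj.mean()) / se)
        p_raw = float(2.0 * sst.t.sf(abs(t), df_err))
        results.append(
            StatResult(
                "bonferroni-t",
                t,
                df_err,
                min(1.0, p_raw * m),
                group_labels=(labels[i], labels[j]),
                p_raw=p_raw,
            )
        )
    return results


def two_way_anova(values, factor_a, factor_b, names=("group", "phase")) -> dict:
    """Two-way ANOVA (Type-II sums of squares) for an unbalanced design.

    Returns a dict with StatResults for both main effects and, when every
    cell of the design is populated, the interaction. With an empty cell the
    additive model is fitted instead and the interaction entry carries a
    ``missing-cell`` flag. If a factor has a single level the problem
    reduces to a one-way ANOVA on the other factor.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "a": factor_a, "b": factor_b})
    la, lb = df["a"].nunique(), df["b"].nunique()
    out: dict = {}
    if la < 2 or lb < 2:
        single, multi, name = ("a", "b", names[1]) if la < 2 else ("b", "a", names[0])
        groups = [sub["y"].to_numpy() for _, sub in df.groupby(multi, sort=True)]
        res = one_way_anova(groups, labels=sorted(df[multi].unique()))
        out[name] = res
        out[names[0] if name == names[1] else names[1]] = None
        out["interaction"] = None
        return out
    cells = df.groupby(["a", "b"], sort=True).size()
    full_grid = la * lb
    has_empty = cells.size < full_grid
    formula = "y ~ C(a) + C(b)" if has_empty else "y ~ C(a) * C(b)"
    model = ols(formula, data=df).fit()
    table = anova_lm(model, typ=2)
    df_err = int(table.loc["Residual", "df"])

    def _extract(row_name, label):
        row = table.loc[row_name]
        return StatResult(
            "two-way-anova",
            float(row["F"]),
            (int(row["df"]), df_err),
            float(row["PR(>F)"]),
            group_labels=(label,),
        )

    out[names[0]] = _extract("C(a)", names[0])
    out[names[1]] = _extract("C(b)", names[1])
    if has_empty:
        out["interaction"] = StatResult(
            "two-way-anova", float("nan"), (0, df_err), float("nan"),
            group_labels=("interaction",), flag="missing-cell",
        )
    else:
        out["interaction"] = _extract("C(a):C(b)", "interaction")
    return out


def kruskal_wallis(groups, labels=None) -> StatResult:
    """Kruskal-Wallis rank H with tie correction, df = k - 1."""
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise DegenerateInputError("need at least two groups")
    if sum(g.size for g in gs) < 3:
        raise DegenerateInputError("total n must be >= 3")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        # complete ties: H = 0 by definition, not an error
        return StatResult("kruskal-wallis", 0.0, len(gs) - 1, 1.0,
                          group_labels=tuple(labels or ()))
    h, p = sst.kruskal(*gs)
    return StatResult("kruskal-wallis", float(h), len(gs) - 1, float(p),
                      group_labels=tuple(labels or ()))


def pearson_r(x, y) -> CorrelationResult:
    """Sample Pearson r with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DegenerateInputError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateInputError("correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input has undefined correlation")
    res = sst.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=int(x.size), p_value=float(res.pvalue))
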