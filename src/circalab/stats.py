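"""Group-comparison layer: assumption-gated two-group tests, factorial ANOVA
with Holm-Sidak step-down follow-ups, and Pearson correlation tables.

The reporting pipeline mirrors common practice in behavioral physiology:
each dataset is gated through Shapiro-Wilk (normality, per group) and
Brown-Forsythe (equal variance, median-centered Levene) checks at alpha; if
both pass, a two-sample Student t-test is used, otherwise the Mann-Whitney
rank-sum test.  Factorial (2- or 3-way) ANOVAs come from an OLS fit with
type-II sums of squares, and the requested pairwise contrasts are adjusted by
the Holm-Sidak step-down:

    p~_(k) = max_{j <= k} [ 1 - (1 - p_(j))^(m - j + 1) ]   (clipped to 1)

for raw p-values sorted ascending, which keeps the family-wise error rate at
alpha while being uniformly more powerful than Bonferroni.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "holm_sidak",
    "gated_two_group_test",
    "factorial_anova",
    "pairwise_holm_sidak",
    "correlation_matrix",
]


@dataclass
class TestReport:
    """One statistical decision: which test ran, why, and what it found."""

    test: str
    statistic: float
    df: float | tuple | None
    p: float
    p_adjusted: float | None = None
    effect: str = ""                 # what was compared
    gate: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def holm_sidak(pvals) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        stepwise = 1.0 - (1.0 - p[idx]) ** (m - k)
        running = max(running, stepwise)
        adj_sorted[k] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def gated_two_group_test(x, y, alpha: float = 0.05, welch: bool = False,
                         effect: str = "") -> TestReport:
    """Two-group comparison routed by normality and equal-variance gates.

    Shapiro-Wilk on each group and Brown-Forsythe across groups, both at
    ``alpha``; if all pass, Student's t-test.  If only the variance gate
    fails and ``welch`` is set, Welch's t-test; otherwise Mann-Whitney.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need n >= 3 per group")
    sw_x = sps.shapiro(x)
    sw_y = sps.shapiro(y)
    bf = sps.levene(x, y, center="median")
    normal = sw_x.pvalue > alpha and sw_y.pvalue > alpha
    equal_var = bf.pvalue > alpha
    gate = {"shapiro_p": (float(sw_x.pvalue), float(sw_y.pvalue)),
            "brown_forsythe_p": float(bf.pvalue),
            "normal": normal, "equal_var": equal_var}
    if normal and equal_var:
        res = sps.ttest_ind(x, y)
        return TestReport("t-test", float(res.statistic), len(x) + len(y) - 2,
                          float(res.pvalue), effect=effect, gate=gate)
    if normal and welch:
        res = sps.ttest_ind(x, y, equal_var=False)
        return TestReport("welch-t", float(res.statistic), float(res.df),
                          float(res.pvalue), effect=effect, gate=gate)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestReport("mann-whitney", float(res.statistic), None,
                      float(res.pvalue), effect=effect, gate=gate)


def factorial_anova(table: pd.DataFrame, dv: str, factors: list[str],
                    subject: str | None = None,
                    followup_within: str | None = None) -> list[TestReport]:
    """Factorial ANOVA (2 or 3 between factors) with optional follow-ups.

    Fits ``dv ~ factor1 * factor2 [* factor3]`` by OLS and reports type-II
    main effects and interactions.  ``subject`` adds a blocking factor for
    repeated-measures-style designs (between/within approximation).  If
    ``followup_within`` names a factor, pairwise contrasts of the *first*
    factor are run inside each level of it and Holm-Sidak adjusted.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not 2 <= len(factors) <= 3:
        raise ValueError("need 2 or 3 factors")
    for f in factors + ([subject] if subject else []):
        if f not in table.columns:
            raise ValueError(f"column {f!r} missing from table")
    counts = table.groupby(factors, observed=True).size()
    if counts.empty or (counts == 0).any() or \
            len(counts) != int(np.prod([table[f].nunique() for f in factors])):
        raise ValueError("design has empty cells; factors must be fully crossed")
    rhs = " * ".join(f"C({f})" for f in factors)
    if subject:
        rhs += f" + C({subject})"
    model = smf.ols(f"{dv} ~ {rhs}", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    reports: list[TestReport] = []
    for name, row in aov.iterrows():
        if name == "Residual":
            continue
        if subject and f"C({subject})" == name:
            continue
        reports.append(TestReport(
            "anova", float(row["F"]),
            (float(row["df"]), float(aov.loc["Residual", "df"])),
            float(row["PR(>F)"]),
            effect=name.replace("C(", "").replace(")", "")))
    if followup_within is not None:
        reports.extend(pairwise_holm_sidak(table, dv, factors[0],
                                           within=followup_within))
    return reports


def pairwise_holm_sidak(table: pd.DataFrame, dv: str, factor: str,
                        within: str | None = None) -> list[TestReport]:
    """Pairwise t-contrasts of ``factor`` (optionally inside each level of
    ``within``), Holm-Sidak adjusted as one family."""
    slices = [(lvl, table[table[within] == lvl]) for lvl in
              sorted(table[within].unique())] if within else [(None, table)]
    raw: list[TestReport] = []
    for lvl, sub in slices:
        levels = sorted(sub[factor].unique())
        for a, b in itertools.combinations(levels, 2):
            xa = sub.loc[sub[factor] == a, dv].to_numpy(dtype=float)
            xb = sub.loc[sub[factor] == b, dv].to_numpy(dtype=float)
            res = sps.ttest_ind(xa, xb)
            label = f"{factor}: {a} vs {b}" + (f" | {within}={lvl}" if within else "")
            raw.append(TestReport("t-contrast", float(res.statistic),
                                  len(xa) + len(xb) - 2, float(res.pvalue),
                                  effect=label))
    adj = holm_sidak([r.p for r in raw])
    for r, a in zip(raw, adj):
        r.p_adjusted = float(a)
    return raw


def correlation_matrix(table: pd.DataFrame, row_metrics: list[str],
                       col_metrics: list[str], min_n: int = 4):
    """Pairwise-complete Pearson correlations with two-sided p per cell.

    Returns ``(r, p, n)`` DataFrames.  Cells with fewer than ``min_n`` paired
    observations or a zero-variance column are NaN (flagged via NaN rather
    than raising, so batch tables never crash).
    """
    r = pd.DataFrame(index=row_metrics, columns=col_metrics, dtype=float)
    p = pd.DataFrame(index=row_metrics, columns=col_metrics, dtype=float)
    n = pd.DataFrame(index=row_metrics, columns=col_metrics, dtype=float)
    for a in row_metrics:
        for b in col_metrics:
            pair = table[[a, b]].dropna()
            n.loc[a, b] = len(pair)
            if len(pair) < min_n or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                r.loc[a, b] = np.nan
                p.loc[a, b] = np.nan
                continue
            res = sps.pearsonr(pair[a], pair[b])
            r.loc[a, b] = float(res.statistic)
            p.loc[a, b] = float(res.pvalue)
    return r, p, n
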