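"""Normality-gated statistical decision tree.

Every comparison first checks its distributional assumptions and then
routes deterministically to a parametric or rank-based test:

* two groups — Shapiro-Wilk on each group; both P > 0.05 selects the
  two-sample t-test, otherwise the two-sided Mann-Whitney U;
* three or more groups — Shapiro-Wilk per group plus Levene's test for
  homogeneity of variances; any normality failure selects Kruskal-Wallis;
  otherwise either classic one-way ANOVA with Tukey HSD (when variances
  are homogeneous and the ``tukey`` post-hoc family is requested) or
  Welch's ANOVA with Games-Howell post-hoc tests;
* correlation — Shapiro-Wilk on both variables; both P > 0.05 selects
  Pearson, otherwise Spearman.

Shapiro-Wilk, Levene, t/U/Kruskal tests and correlations delegate to
scipy; Welch's ANOVA and Games-Howell pairwise comparisons are computed
here in closed form (scipy exposes neither), with P values from the
studentized-range distribution.  The rank-sum test enumerates the exact
permutation distribution for small tie-free samples and falls back to the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_GATE = 0.05  # normality / homogeneity gate threshold


@dataclass
class GateDecision:
    """Outcome of a gated comparison: gate P values, branch, and result."""

    normality_p: tuple[float, ...]
    chosen_test: str
    statistic: float
    p_value: float
    variance_homogeneity_p: float | None = None
    df: tuple[float, ...] | None = None
    posthoc: pd.DataFrame | None = None


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro-Wilk P value; a zero-variance vector counts as non-normal."""
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def compare_two_groups(x, y, alpha: float = ALPHA_GATE) -> GateDecision:
    """Two-group comparison behind the Shapiro-Wilk gate.

    Both groups normal at P > ``alpha``: independent two-sample t-test;
    otherwise two-sided Mann-Whitney U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    px, py = _shapiro_p(x), _shapiro_p(y)
    if px > alpha and py > alpha:
        res = sps.ttest_ind(x, y)
        return GateDecision(
            normality_p=(px, py),
            chosen_test="t_test",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            df=(float(res.df),),
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return GateDecision(
        normality_p=(px, py),
        chosen_test="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, df1, df2, p)``.  Group means are weighted by
    ``n_i / s_i^2``; the denominator degrees of freedom follow the
    Welch-Satterthwaite correction.
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    if np.any(v == 0):
        raise ValueError("Welch ANOVA undefined for a zero-variance group")
    w = n / v
    big_w = w.sum()
    mw = (w * m).sum() / big_w
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tmp = (((1 - w / big_w) ** 2) / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    f = num / den
    df1 = float(k - 1)
    df2 = (k**2 - 1) / (3 * tmp)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


def games_howell(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (unequal variances).

    For each pair the Welch t statistic is referred to the
    studentized-range distribution with ``q = |t| * sqrt(2)`` and
    Welch-Satterthwaite degrees of freedom.
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([np.mean(g) for g in groups])
    v = np.array([np.var(g, ddof=1) for g in groups])
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        se2 = v[i] / n[i] + v[j] / n[j]
        t = (m[i] - m[j]) / math.sqrt(se2)
        df = se2**2 / (
            (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
        )
        p = float(sps.studentized_range.sf(abs(t) * math.sqrt(2), k, df))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": m[i] - m[j],
                "t": t,
                "df": df,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _tukey_table(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                "statistic": float(res.statistic[i, j]),
                "p_value": float(res.pvalue[i, j]),
            }
        )
    return pd.DataFrame(rows)


def compare_k_groups(
    groups,
    posthoc_family: str = "games_howell",
    labels: list[str] | None = None,
    alpha: float = ALPHA_GATE,
) -> GateDecision:
    """K-group (k >= 3) comparison behind the normality/homogeneity gate.

    Any group failing Shapiro-Wilk routes to Kruskal-Wallis.  With all
    groups normal, ``posthoc_family="tukey"`` runs classic ANOVA + Tukey
    HSD when Levene's test passes and escalates to Welch + Games-Howell
    when it fails; ``posthoc_family="games_howell"`` always uses Welch's
    ANOVA with Games-Howell post hocs (valid under heteroscedasticity).
    """
    if posthoc_family not in ("tukey", "games_howell"):
        raise ValueError(f"unknown posthoc family {posthoc_family!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("compare_k_groups needs k >= 3 (use compare_two_groups)")
    if any(len(g) < 3 for g in groups):
        raise ValueError("each group needs n >= 3")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    norm_p = tuple(_shapiro_p(g) for g in groups)
    lev_p = float(sps.levene(*groups, center="mean").pvalue)

    if any(p <= alpha for p in norm_p):
        h, p = sps.kruskal(*groups)
        return GateDecision(
            normality_p=norm_p,
            variance_homogeneity_p=lev_p,
            chosen_test="kruskal_wallis",
            statistic=float(h),
            p_value=float(p),
        )
    if posthoc_family == "tukey" and lev_p > alpha:
        f, p = sps.f_oneway(*groups)
        return GateDecision(
            normality_p=norm_p,
            variance_homogeneity_p=lev_p,
            chosen_test="anova",
            statistic=float(f),
            p_value=float(p),
            df=(float(len(groups) - 1), float(sum(map(len, groups)) - len(groups))),
            posthoc=_tukey_table(groups, labels),
        )
    f, df1, df2, p = welch_anova(groups)
    return GateDecision(
        normality_p=norm_p,
        variance_homogeneity_p=lev_p,
        chosen_test="welch_anova",
        statistic=f,
        p_value=p,
        df=(df1, df2),
        posthoc=games_howell(groups, labels),
    )


def gated_correlation(x, y, alpha: float = ALPHA_GATE) -> tuple[str, float, float]:
    """Correlation behind the Shapiro-Wilk gate.

    Returns ``(method, coefficient, p_value)`` with method ``"pearson"``
    when both variables pass normality at P > ``alpha``, ``"spearman"``
    otherwise, and ``"undefined"`` (NaN coefficient) when either variable
    is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ("undefined", float("nan"), float("nan"))
    px, py = _shapiro_p(x), _shapiro_p(y)
    if px > alpha and py > alpha:
        r, p = sps.pearsonr(x, y)
        return ("pearson", float(r), float(p))
    r, p = sps.spearmanr(x, y)
    return ("spearman", float(r), float(p))


def _exact_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum P by enumerating all label assignments."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(n1 + n2)
    ranks[order] = np.arange(1, n1 + n2 + 1)
    w_obs = ranks[:n1].sum()
    dist = [
        sum(combo)
        for combo in itertools.combinations(ranks, n1)
    ]
    dist = np.array(dist)
    total = len(dist)
    p_le = np.count_nonzero(dist <= w_obs) / total
    p_ge = np.count_nonzero(dist >= w_obs) / total
    p = min(1.0, 2 * min(p_le, p_ge))
    u = w_obs - n1 * (n1 + 1) / 2
    return float(u), float(p)


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; tie-corrected normal
    approximation (with continuity correction) otherwise.  Returns
    ``(U, p)`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= exact_max_n:
        return _exact_rank_sum(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_raw_and_log10(x, y) -> dict[str, GateDecision]:
    """Run the gated two-group comparison on raw and log10-scaled loads.

    Load-like quantities are often closer to log-normal; both views are
    reported so the branch taken on each scale is explicit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = {"raw": compare_two_groups(x, y)}
    if (x > 0).all() and (y > 0).all():
        out["log10"] = compare_two_groups(np.log10(x), np.log10(y))
    return out
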