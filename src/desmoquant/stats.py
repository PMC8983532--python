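"""Statistical comparisons used by all quantification modules.

Two-group comparisons use the two-tailed Student's t test, falling back to
the Wilcoxon-Mann-Whitney rank-sum test when an equal-variance pre-test
(two-sided F test) fails — the ``test='auto'`` rule.  Rank-sum p-values are
computed by exhaustive permutation enumeration (with midranks for ties) when
both groups have at most 8 samples, and by the tie-corrected normal
approximation with continuity correction otherwise.  Multi-group
comparisons use one-way ANOVA followed by all pairwise t tests with
Bonferroni adjustment.

Significance stars default to the figure-legend convention
(* p < 0.05, ** p < 0.01, *** p < 0.001); the stricter *** threshold of
0.005 used in some methods descriptions can be selected via ``thresholds``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: default significance thresholds for *, **, ***
DEFAULT_THRESHOLDS = (0.05, 0.01, 0.001)
#: alternative convention with *** at p < 0.005
METHODS_THRESHOLDS = (0.05, 0.01, 0.005)

_EXACT_MAX_N = 8


def significance_stars(p: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Map a p-value to 'ns' / '*' / '**' / '***' (strict inequalities)."""
    t1, t2, t3 = thresholds
    if p < t3:
        return "***"
    if p < t2:
        return "**"
    if p < t1:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple
    significance_stars: str
    group_pair: tuple | None = None


def _exact_mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Ties are handled with midranks; the two-sided p-value is the fraction
    of the C(n1+n2, n1) group assignments whose U statistic deviates from
    its null mean by at least as much as the observed one.
    """
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            extreme += 1
    return float(u_obs), extreme / total


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if max(len(a), len(b)) <= _EXACT_MAX_N:
        return _exact_mann_whitney(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: both groups constant -> p is 1 (equal) or 0 (different)
        return (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def _variances_equal(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> bool:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        return va == vb
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p_one = sps.f.sf(f, dfa, dfb) if f >= 1 else sps.f.cdf(f, dfa, dfb)
    return 2 * min(p_one, 0.5) >= alpha


def compare_groups(a, b, test: str = "auto",
                   thresholds=DEFAULT_THRESHOLDS) -> GroupComparison:
    """Two-tailed comparison of two samples.

    ``test`` is ``'student_t'``, ``'mann_whitney'`` or ``'auto'`` (t test
    when a two-sided F test accepts equal variances at alpha = 0.05, the
    rank-sum test otherwise).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if test == "auto":
        if len(a) < 2 or len(b) < 2:
            test = "mann_whitney"
        else:
            test = "student_t" if _variances_equal(a, b) else "mann_whitney"
    if test == "student_t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("the t test needs at least 2 samples per group")
        stat, p = _student_t(a, b)
    elif test == "mann_whitney":
        stat, p = _mann_whitney(a, b)
    else:
        raise ValueError("test must be 'auto', 'student_t' or 'mann_whitney'")
    return GroupComparison(test_name=test, statistic=stat, p_value=p,
                           n_per_group=(len(a), len(b)),
                           significance_stars=significance_stars(p, thresholds))


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    comparisons: list     # pairwise GroupComparison with Bonferroni-adjusted p


def anova_bonferroni(groups, group_names=None,
                     thresholds=DEFAULT_THRESHOLDS) -> AnovaResult:
    """One-way ANOVA followed by Bonferroni-adjusted pairwise t tests.

    ``groups`` is a list of >= 3 samples (each with n >= 2); for 2 groups
    use :func:`compare_groups`.  Each pairwise raw p-value is multiplied by
    the number of pairs and capped at 1, so adjusted p >= raw p always.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 3:
        raise ValueError("anova_bonferroni needs >= 3 groups; "
                         "use compare_groups for two groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 samples")
    if group_names is None:
        group_names = [f"group{i}" for i in range(len(arrays))]

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        f_stat, p_omni = 0.0, 1.0
    else:
        res = sps.f_oneway(*arrays)
        f_stat, p_omni = float(res.statistic), float(res.pvalue)

    k = len(arrays) * (len(arrays) - 1) // 2
    comparisons = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(arrays), 2):
        stat, p_raw = _student_t(gi, gj)
        p_adj = min(1.0, p_raw * k)
        comparisons.append(GroupComparison(
            test_name="anova_bonferroni", statistic=stat, p_value=p_adj,
            n_per_group=(len(gi), len(gj)),
            significance_stars=significance_stars(p_adj, thresholds),
            group_pair=(group_names[i], group_names[j]),
        ))
    return AnovaResult(f_statistic=f_stat, p_value=p_omni, comparisons=comparisons)
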