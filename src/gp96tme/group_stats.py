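"""Nonparametric group-comparison utilities shared by all analyses.

Two-group comparisons use the Mann–Whitney U test, multi-group
comparisons the Kruskal–Wallis H test with Bonferroni-adjusted pairwise
post hocs, and false-discovery-rate control uses Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# below this combined sample size (and with no ties) the exact U null
# distribution is enumerated instead of the normal approximation
EXACT_MW_MAX_N = 20


@dataclass
class GroupComparisonResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    method: str
    adjusted_p: float | None = None
    adjustment: str | None = None


def mann_whitney(a, b) -> GroupComparisonResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration for small tie-free samples (combined n below
    :data:`EXACT_MW_MAX_N`), tie-corrected normal approximation otherwise.
    The reported statistic is U for the first sample.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size < EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparisonResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(a.size, b.size),
        method=f"mann-whitney-{method}",
    )


def kruskal_wallis_posthoc(groups) -> tuple[GroupComparisonResult, list[dict]]:
    """Kruskal–Wallis omnibus test plus Bonferroni-adjusted pairwise
    Mann–Whitney post hocs.

    Returns ``(omnibus, pairwise)`` where each pairwise entry records the
    group index pair, raw p and Bonferroni-adjusted p (raw × number of
    comparisons, capped at 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_wallis_posthoc needs k >= 3 groups; use mann_whitney for 2")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size < 2:
        raise ValueError("all observations identical: H statistic undefined (zero variance)")
    h, p = stats.kruskal(*groups)
    omnibus = GroupComparisonResult(
        statistic=float(h), p_value=float(p),
        group_sizes=tuple(g.size for g in groups),
        method="kruskal-wallis",
    )
    k = len(groups)
    n_comp = k * (k - 1) // 2
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            r = mann_whitney(groups[i], groups[j])
            pairwise.append({
                "groups": (i, j),
                "statistic": r.statistic,
                "p_raw": r.p_value,
                "p_bonferroni": min(r.p_value * n_comp, 1.0),
                "n": r.group_sizes,
            })
    return omnibus, pairwise


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
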