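"""Transcriptomic arm: DEG filtering, interferon-pathway-activity scoring
and the conditioning analysis probing interferon mediation.

The IPA (interferon pathway activity) score of a sample is the
arithmetic mean of log2(TPM + 0.1) over the panel of differentially
expressed genes shared by the hallmark IFN-α and IFN-γ response sets.
If the gp96 gene (HSP90B1) correlates with T-cell markers *because*
both track interferon activity, then restricting the cohort to samples
with nearly constant IPA score should shrink those correlations —
which the conditioning analysis quantifies against same-size random
subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ANCHOR_GENE = "HSP90B1"
MARKER_GENES = ("CD8A", "CD4", "PDCD1")
TPM_PSEUDOCOUNT = 0.1


def filter_degs(deg_table: pd.DataFrame, fc_threshold: float = 2.0,
                padj_threshold: float = 0.01) -> list[str]:
    """Genes with |fold change| strictly > ``fc_threshold`` (two-sided on
    |log2FC|) and adjusted p strictly < ``padj_threshold``.

    ``deg_table`` is indexed by gene symbol with columns log2fc, padj.
    """
    if deg_table.empty:
        raise ValueError("DEG table is empty")
    lfc = deg_table["log2fc"].astype(float)
    padj = deg_table["padj"].astype(float)
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")
    keep = (lfc.abs() > np.log2(fc_threshold)) & (padj < padj_threshold)
    return sorted(deg_table.index[keep])


def shared_genes(degs, set_a, set_b) -> list[str]:
    """DEGs present in both gene sets, sorted for order stability."""
    return sorted(set(degs) & set(set_a) & set(set_b))


def ipa_score(expr: pd.DataFrame, genes) -> tuple[pd.Series, list[str]]:
    """Per-sample mean of log2(TPM + 0.1) over the listed genes.

    ``expr`` is genes × samples (TPM >= 0). Returns (scores, missing):
    genes absent from the matrix are skipped and reported back.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.index]
    missing = [g for g in genes if g not in expr.index]
    if not present:
        raise ValueError("none of the requested genes are present in the matrix")
    sub = expr.loc[present].astype(float)
    if (sub < 0).any().any():
        raise ValueError("TPM values must be non-negative")
    scores = np.log2(sub + TPM_PSEUDOCOUNT).mean(axis=0)
    scores.name = "ipa_score"
    return scores, missing


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_correlation requires paired vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class MarkerConditioning:
    rho_random: float      # mean Spearman over random subsets
    rho_mid: float         # Spearman within the mid-IPA subset
    delta: float           # |rho_random| - |rho_mid|
    p_reduction: float


@dataclass
class ConditioningResult:
    markers: dict[str, MarkerConditioning]
    subset_size: int
    n_random: int
    ipa_var_mid: float
    ipa_var_random_mean: float
    full_cohort_rho: dict[str, float] = field(default_factory=dict)


def mid_ipa_subset(ipa: pd.Series, subset_size: int) -> pd.Index:
    """The ``subset_size`` samples whose IPA ranks are centered on the
    median rank — the contiguous-in-rank window with minimal IPA spread."""
    n = ipa.size
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds cohort size {n}")
    order = ipa.sort_values(kind="stable").index
    start = (n - subset_size) // 2
    return order[start:start + subset_size]


def conditioning_analysis(
    expr: pd.DataFrame,
    ipa: pd.Series,
    anchor_gene: str = ANCHOR_GENE,
    markers=MARKER_GENES,
    subset_size: int = 200,
    n_random: int = 1000,
    seed: int | None = None,
) -> ConditioningResult:
    """Contrast anchor-marker correlations in the mid-IPA subset against
    random subsets of the same size.

    For each marker, ``rho_mid`` is the Spearman correlation of
    log2(TPM+0.1) of the anchor with the marker inside the mid-IPA
    subset, and the reference distribution is the correlation over
    ``n_random`` seeded random subsets; ``p_reduction`` is the
    +1-corrected fraction of random subsets with |rho| <= |rho_mid|
    (small p: the mid-IPA restriction shrinks the correlation more than
    chance subsetting does).
    """
    if anchor_gene not in expr.index:
        raise ValueError(f"anchor gene {anchor_gene!r} absent from expression matrix")
    markers = list(markers)
    absent = [m for m in markers if m not in expr.index]
    if absent:
        raise ValueError(f"marker genes absent from expression matrix: {absent}")
    ipa = ipa.loc[expr.columns]
    n = expr.shape[1]

    log_expr = np.log2(expr.loc[[anchor_gene] + markers].astype(float)
                       + TPM_PSEUDOCOUNT)
    mid = mid_ipa_subset(ipa, subset_size)
    mid_pos = expr.columns.get_indexer(mid)

    anchor = log_expr.loc[anchor_gene].to_numpy()
    marker_arr = {m: log_expr.loc[m].to_numpy() for m in markers}

    rng = np.random.default_rng(seed)
    subsets = [rng.choice(n, size=subset_size, replace=False)
               for _ in range(n_random)]

    ipa_arr = ipa.to_numpy(float)
    result: dict[str, MarkerConditioning] = {}
    full_rho = {}
    for m in markers:
        rho_mid, _ = spearman_correlation(anchor[mid_pos], marker_arr[m][mid_pos])
        rhos = np.array([
            stats.spearmanr(anchor[idx], marker_arr[m][idx]).statistic
            for idx in subsets])
        n_leq = int((np.abs(rhos) <= np.abs(rho_mid) + 1e-15).sum())
        result[m] = MarkerConditioning(
            rho_random=float(rhos.mean()),
            rho_mid=float(rho_mid),
            delta=float(np.abs(rhos.mean()) - np.abs(rho_mid)),
            p_reduction=(1 + n_leq) / (n_random + 1),
        )
        full_rho[m], _ = spearman_correlation(anchor, marker_arr[m])
    return ConditioningResult(
        markers=result,
        subset_size=subset_size,
        n_random=n_random,
        ipa_var_mid=float(np.var(ipa_arr[mid_pos])),
        ipa_var_random_mean=float(np.mean([np.var(ipa_arr[idx]) for idx in subsets])),
        full_cohort_rho=full_rho,
    )
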