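"""Co-expression structure of High-CV genes and its genomic localisation.

High-CV genes are tested for concordant expression beyond chance: their
pairwise Pearson correlations are compared (two-sided Wilcoxon rank-sum)
against a null built by independently permuting each gene's values across
cells.  Tight clusters come from hierarchical clustering on 1 - r with a cut
at 1 - threshold; complete linkage makes the cut a guarantee on the minimum
within-cluster correlation.  TAD co-occurrence and genome-neighbourhood
co-occurrence of High-CV genes use label-permutation nulls with add-one
empirical p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .results import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionResult",
    "GeneCluster",
    "pairwise_correlations",
    "permutation_null",
    "real_vs_null_test",
    "run_coexpression_test",
    "extract_clusters",
    "cluster_cell_specificity",
    "tad_cooccurrence",
    "neighbour_cooccurrence",
]


@dataclass
class CoexpressionResult:
    gene_ids: list[str]
    corr: np.ndarray  # symmetric, unit diagonal
    null_corrs: np.ndarray
    wilcoxon_p: float
    n_permutations: int
    seed: int
    n_constant_dropped: int = 0


@dataclass
class GeneCluster:
    cluster_id: int
    gene_ids: set[str]
    min_internal_corr: float


def pairwise_correlations(matrix: ExpressionMatrix) -> tuple[list[str], np.ndarray, int]:
    """Pearson correlations between all gene pairs, on raw FPKM across cells.

    Constant genes (undefined correlation) are excluded; returns the retained
    gene ids, the correlation matrix and the number of genes dropped.
    """
    if matrix.n_genes < 2 or matrix.n_cells < 3:
        raise ValueError("need at least 2 genes and 3 cells")
    sds = matrix.values.std(axis=1)
    ok = sds > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("pairwise_correlations: dropped %d constant genes", n_dropped)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes")
    gene_ids = [g for g, k in zip(matrix.gene_ids, ok) if k]
    corr = np.corrcoef(matrix.values[ok])
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return gene_ids, corr, n_dropped


def shuffle_within_genes(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each gene's values across cells (multisets kept)."""
    return rng.permuted(values, axis=1)


def permutation_null(
    matrix: ExpressionMatrix, n_permutations: int, seed: int
) -> np.ndarray:
    """Pooled pairwise correlations after shuffling each gene across cells.

    Every permutation independently permutes each gene's values between cells
    (preserving its value multiset), recomputes all pairwise correlations and
    pools the upper triangles.  Deterministic given the seed.
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_permutations):
        shuffled = shuffle_within_genes(matrix.values, rng)
        sds = shuffled.std(axis=1)
        ok = sds > 0
        if ok.sum() < 2:
            continue
        corr = np.corrcoef(shuffled[ok])
        pooled.append(corr[np.triu_indices(int(ok.sum()), k=1)])
    if not pooled:
        return np.empty(0)
    null = np.concatenate(pooled)
    np.clip(null, -1.0, 1.0, out=null)
    return null


def real_vs_null_test(corr: np.ndarray, null_corrs: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: real upper-triangle correlations vs null."""
    real = corr[np.triu_indices(corr.shape[0], k=1)]
    if real.size == 0 or null_corrs.size == 0:
        raise ValueError("both correlation samples must be non-empty")
    _, p = stats.mannwhitneyu(real, null_corrs, alternative="two-sided")
    return float(p)


def run_coexpression_test(
    matrix: ExpressionMatrix, n_permutations: int = 100, seed: int = 0
) -> CoexpressionResult:
    """Correlations of a High-CV submatrix, permutation null and Wilcoxon test."""
    gene_ids, corr, n_dropped = pairwise_correlations(matrix)
    null = permutation_null(matrix.subset_genes(gene_ids), n_permutations, seed)
    p = real_vs_null_test(corr, null)
    return CoexpressionResult(gene_ids, corr, null, p, n_permutations, seed, n_dropped)


def extract_clusters(
    gene_ids: list[str],
    corr: np.ndarray,
    threshold: float = 0.95,
    method: str = "complete",
) -> list[GeneCluster]:
    """Hierarchical clustering on 1 - r, tree cut at 1 - threshold.

    Returns clusters of size >= 2 with their minimum internal pairwise
    correlation; with complete linkage that minimum is guaranteed to be at
    least ``threshold``.
    """
    if method not in ("complete", "average"):
        raise ValueError("linkage must be 'complete' or 'average'")
    if corr.shape[0] != len(gene_ids):
        raise ValueError("corr shape does not match gene_ids")
    if len(gene_ids) < 2:
        return []
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    tree = linkage(condensed, method=method)
    labels = fcluster(tree, t=1.0 - threshold, criterion="distance")
    clusters = []
    for cluster_id in sorted(np.unique(labels)):
        members = np.flatnonzero(labels == cluster_id)
        if members.size < 2:
            continue
        sub = corr[np.ix_(members, members)]
        min_corr = float(sub[np.triu_indices(members.size, k=1)].min())
        clusters.append(
            GeneCluster(
                cluster_id=len(clusters),
                gene_ids={gene_ids[i] for i in members},
                min_internal_corr=min_corr,
            )
        )
    return clusters


def cluster_cell_specificity(
    matrix: ExpressionMatrix, clusters: list[GeneCluster]
) -> pd.DataFrame:
    """Per-cluster mean expression per cell, the dominant cell, and dominance.

    Dominance is the top cell mean divided by the median cell mean (inf when
    the median is 0); a burst-driven cluster is dominated by its burst cell.
    """
    rows = []
    for cluster in clusters:
        sub = matrix.subset_genes(sorted(cluster.gene_ids))
        profile = sub.values.mean(axis=0)
        top = int(np.argmax(profile))
        median = float(np.median(profile))
        dominance = float(profile[top] / median) if median > 0 else float("inf")
        rows.append(
            {
                "cluster_id": cluster.cluster_id,
                "n_genes": len(cluster.gene_ids),
                "top_cell": matrix.cell_ids[top],
                "top_cell_mean": float(profile[top]),
                "median_cell_mean": median,
                "dominance_ratio": dominance,
            }
        )
    return pd.DataFrame(rows)


def _label_permutation_p(
    observed: float, labels: np.ndarray, statistic, n_permutations: int, seed: int
) -> tuple[float, np.ndarray]:
    """One-sided add-one empirical p for a statistic under label shuffles."""
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    work = labels.copy()
    for i in range(n_permutations):
        rng.shuffle(work)
        null[i] = statistic(work)
    p = (1.0 + float((null >= observed).sum())) / (n_permutations + 1.0)
    return p, null


def tad_cooccurrence(
    annotations: pd.DataFrame,
    high_cv,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Do High-CV genes co-occupy TADs more than random gene labels would?

    Statistic: number of TADs containing >= 2 High-CV genes; null from
    permuting High-CV labels across TAD-annotated genes.
    """
    test_name = "tad_cooccurrence"
    if "tad_id" not in annotations.columns:
        return EnrichmentResult.not_evaluated(test_name, reason="no TAD annotations")
    tads = annotations["tad_id"].dropna()
    if len(tads) < 2:
        return EnrichmentResult.not_evaluated(test_name, reason="fewer than 2 TAD-annotated genes")
    codes = pd.Categorical(tads).codes
    labels = tads.index.isin(set(high_cv)).astype(bool)
    n_tads = int(codes.max()) + 1

    def statistic(lab: np.ndarray) -> float:
        return float((np.bincount(codes[lab], minlength=n_tads) >= 2).sum())

    observed = statistic(labels)
    p, null = _label_permutation_p(observed, labels, statistic, n_permutations, seed)
    return EnrichmentResult(
        test_name=test_name,
        statistic=observed,
        p_value=p,
        n_a=int(labels.sum()),
        n_b=int(len(labels) - labels.sum()),
        effect_direction="enriched" if observed > float(null.mean()) else "none",
        extras={"n_permutations": n_permutations, "null_mean": float(null.mean())},
    )


def neighbour_cooccurrence(
    annotations: pd.DataFrame,
    high_cv,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Do High-CV genes sit next to each other in genome order?

    Statistic: adjacent same-chromosome gene pairs that are both High CV;
    null from permuting High-CV labels across positioned genes.
    """
    test_name = "neighbour_cooccurrence"
    required = {"chrom", "tss"}
    if not required.issubset(annotations.columns):
        return EnrichmentResult.not_evaluated(test_name, reason="no gene positions")
    pos = annotations[["chrom", "tss"]].dropna()
    if len(pos) < 2:
        return EnrichmentResult.not_evaluated(test_name, reason="fewer than 2 positioned genes")
    pos = pos.sort_values(["chrom", "tss"])
    same_chrom = (pos["chrom"].to_numpy()[:-1] == pos["chrom"].to_numpy()[1:])
    labels = pos.index.isin(set(high_cv)).astype(bool)

    def statistic(lab: np.ndarray) -> float:
        return float((lab[:-1] & lab[1:] & same_chrom).sum())

    observed = statistic(labels)
    p, null = _label_permutation_p(observed, labels, statistic, n_permutations, seed)
    return EnrichmentResult(
        test_name=test_name,
        statistic=observed,
        p_value=p,
        n_a=int(labels.sum()),
        n_b=int(len(labels) - labels.sum()),
        effect_direction="enriched" if observed > float(null.mean()) else "none",
        extras={"n_permutations": n_permutations, "null_mean": float(null.mean())},
    )
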