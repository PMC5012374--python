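"""Regulatory and chromatin correlates of expression variability.

Relates the CV classes to promoter occupancy by transcription/epigenetic
factors (ChIP-seq peaks in TSS +/- 1 kb windows), miRNA-target and
protein-interaction degree bins, bivalent vs active chromatin, and promoter
sequence class (CpG island, TATA box).  Factor-specific binding preference for
High-CV genes is a one-sided hypergeometric upper-tail test; "exclusive"
preference additionally requires no enrichment in the Non-High-CV set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cv_stats import MIN_GROUP, compare_group_cv
from .io import IntervalSet
from .results import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterWindow",
    "make_promoters",
    "count_factors_per_promoter",
    "occupancy_vs_cv",
    "factor_preference_test",
    "exclusive_preference_test",
    "binned_degree_vs_cv",
    "bivalency_vs_cv",
    "promoter_class_vs_cv",
    "add_bh_fdr",
]


@dataclass
class PromoterWindow:
    """TSS-centred window in 0-based half-open coordinates, clipped at 0."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid promoter window {self.start}-{self.end}")


def make_promoters(annotations: pd.DataFrame, flank: int = 1000) -> list[PromoterWindow]:
    """Promoter windows [tss - flank, tss + flank), identical for both strands.

    Genes lacking position fields are skipped; the count is logged.
    """
    required = {"chrom", "tss", "strand"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotations missing position columns {sorted(required)}")
    promoters = []
    n_skipped = 0
    for gene_id, row in annotations.iterrows():
        if pd.isna(row["chrom"]) or pd.isna(row["tss"]) or pd.isna(row["strand"]):
            n_skipped += 1
            continue
        tss = int(row["tss"])
        promoters.append(
            PromoterWindow(
                gene_id=str(gene_id),
                chrom=str(row["chrom"]),
                start=max(0, tss - flank),
                end=tss + flank,
                strand=str(row["strand"]),
            )
        )
    if n_skipped:
        logger.info("make_promoters: skipped %d genes without positions", n_skipped)
    return promoters


def count_factors_per_promoter(
    promoters: list[PromoterWindow], peak_sets: list[IntervalSet]
) -> dict[str, int]:
    """Number of *distinct* factors with at least one peak in each promoter.

    Multiple peaks of one factor count once.  Overlap is half-open: a peak
    touching a promoter edge does not overlap.
    """
    trees: list[dict[str, IntervalTree]] = []
    for peaks in peak_sets:
        by_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end in peaks.intervals:
            by_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        trees.append(by_chrom)
    counts: dict[str, int] = {}
    for prom in promoters:
        n = 0
        for by_chrom in trees:
            tree = by_chrom.get(prom.chrom)
            if tree is not None and tree.overlap(prom.start, prom.end):
                n += 1
        counts[prom.gene_id] = n
    return counts


def occupancy_vs_cv(
    stats_table: pd.DataFrame,
    factor_counts: dict[str, int],
    cut: int = 10,
    min_group: int = MIN_GROUP,
) -> EnrichmentResult:
    """Welch t-test: CV of genes bound by more than ``cut`` factors vs fewer.

    Genes bound by exactly ``cut`` factors are excluded (the contrast is
    "less than" vs "more than"); the exclusion count is logged.  Group A is
    the high-occupancy group, so an anti-correlation between occupancy and
    variability reports direction ``lower_cv``.
    """
    counts = pd.Series(factor_counts)
    high = set(counts.index[counts > cut])
    low = set(counts.index[counts < cut])
    n_at_cut = int((counts == cut).sum())
    if n_at_cut:
        logger.info("occupancy_vs_cv: excluded %d genes bound by exactly %d factors", n_at_cut, cut)
    result = compare_group_cv(
        stats_table, high, low, min_group=min_group, test_name=f"occupancy_gt{cut}_vs_lt{cut}"
    )
    result.extras["n_at_cut"] = n_at_cut
    return result


def factor_preference_test(
    factor_targets, high_cv, universe, test_name: str = "factor_preference"
) -> EnrichmentResult:
    """Upper-tail hypergeometric test for factor binding preferring High-CV genes.

    p = P(X >= k) where X counts High-CV genes among |targets| draws without
    replacement from a universe containing |high_cv| of them and k is the
    observed overlap.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = set(factor_targets)
    high = set(high_cv)
    if not targets <= universe or not high <= universe:
        raise ValueError("targets and high_cv must be subsets of the universe")
    n_univ, n_high, n_targ = len(universe), len(high), len(targets)
    k = len(targets & high)
    p = float(stats.hypergeom.sf(k - 1, n_univ, n_high, n_targ))
    expected = n_targ * n_high / n_univ
    direction = "enriched" if k > expected else ("depleted" if k < expected else "none")
    return EnrichmentResult(
        test_name=test_name,
        statistic=float(k),
        p_value=min(p, 1.0),
        n_a=n_targ,
        n_b=n_high,
        effect_direction=direction,
        extras={"n_universe": n_univ, "expected_overlap": expected},
    )


def exclusive_preference_test(
    factor_targets, high_cv, non_high_cv, universe, alpha: float = 0.05,
    test_name: str = "factor",
) -> tuple[EnrichmentResult, EnrichmentResult, bool]:
    """Binding preference exclusive to High-CV genes.

    Exclusive = significantly enriched among High-CV targets AND not
    significantly enriched among Non-High-CV targets; both sub-tests are
    returned for reporting.
    """
    res_high = factor_preference_test(
        factor_targets, high_cv, universe, test_name=f"{test_name}:high_cv"
    )
    res_non = factor_preference_test(
        factor_targets, non_high_cv, universe, test_name=f"{test_name}:non_high_cv"
    )
    exclusive = res_high.p_value < alpha and not res_non.p_value < alpha
    return res_high, res_non, exclusive


def binned_degree_vs_cv(
    stats_table: pd.DataFrame,
    degrees: dict[str, int] | pd.Series,
    bin_uppers,
    min_group: int = MIN_GROUP,
    test_name: str = "degree",
) -> tuple[pd.DataFrame, list[EnrichmentResult]]:
    """Bin genes by interaction degree and t-test CV between adjacent bins.

    ``bin_uppers`` are the strictly increasing inclusive upper edges of all
    but the last bin; the last bin is open-ended (e.g. ``(50, 100)`` gives
    bins 1-50, 51-100, >100 and ``(1, 2, 3)`` gives 1, 2, 3, >3).  Genes with
    degree 0 are excluded (bins start at 1) and the exclusion is logged.
    """
    uppers = list(bin_uppers)
    if any(b >= c for b, c in zip(uppers, uppers[1:])):
        raise ValueError("bin edges must be strictly increasing")
    degrees = pd.Series(degrees).dropna().astype(int)
    n_zero = int((degrees < 1).sum())
    if n_zero:
        logger.info("binned_degree_vs_cv: excluded %d genes with degree 0", n_zero)
    degrees = degrees[degrees >= 1]

    edges = [0] + uppers + [np.inf]
    labels = [
        (f"{lo + 1}" if lo + 1 == hi else f"{lo + 1}-{hi}") if np.isfinite(hi) else f">{lo}"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    bin_of = pd.cut(degrees, bins=edges, labels=labels)

    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    rows, members = [], []
    for label in labels:
        genes = set(bin_of.index[bin_of == label]) & set(eligible.index)
        cvs = eligible.loc[sorted(genes), "cv"]
        rows.append({"bin": label, "n": len(genes), "mean_cv": float(cvs.mean()) if len(genes) else np.nan})
        members.append(genes)
    summary = pd.DataFrame(rows)

    tests = [
        compare_group_cv(
            stats_table, members[i], members[i + 1], min_group=min_group,
            test_name=f"{test_name}:{labels[i]}_vs_{labels[i + 1]}",
        )
        for i in range(len(labels) - 1)
    ]
    return summary, tests


def bivalency_vs_cv(
    stats_table: pd.DataFrame,
    annotations: pd.DataFrame,
    min_group: int = MIN_GROUP,
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Bivalent vs active promoters, two ways.

    Returns (a) a Welch t-test between the CVs of bivalent and active genes
    and (b) a hypergeometric overlap test of the bivalent set against the
    High-CV set over the retained universe.
    """
    if "bivalency" not in annotations.columns:
        return (
            EnrichmentResult.not_evaluated("bivalent_vs_active_cv", reason="no bivalency labels"),
            EnrichmentResult.not_evaluated("bivalent_highcv_overlap", reason="no bivalency labels"),
        )
    labels = annotations["bivalency"]
    bivalent = set(labels.index[labels == "bivalent"])
    active = set(labels.index[labels == "active"])
    if not bivalent or not active:
        return (
            EnrichmentResult.not_evaluated(
                "bivalent_vs_active_cv", len(bivalent), len(active), reason="a class is absent"
            ),
            EnrichmentResult.not_evaluated(
                "bivalent_highcv_overlap", len(bivalent), len(active), reason="a class is absent"
            ),
        )
    t_result = compare_group_cv(
        stats_table, bivalent, active, min_group=min_group, test_name="bivalent_vs_active_cv"
    )
    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    universe = set(eligible.index)
    high = set(eligible.index[eligible["high_cv"]])
    hg_result = factor_preference_test(
        bivalent & universe, high, universe, test_name="bivalent_highcv_overlap"
    )
    return t_result, hg_result


def promoter_class_vs_cv(
    stats_table: pd.DataFrame,
    annotations: pd.DataFrame,
    feature: str,
    min_group: int = MIN_GROUP,
) -> EnrichmentResult:
    """CV of feature-positive vs feature-negative promoters (cpg_island or tata)."""
    if feature not in ("cpg_island", "tata"):
        raise ValueError("feature must be 'cpg_island' or 'tata'")
    test_name = f"{feature}_vs_cv"
    if feature not in annotations.columns:
        return EnrichmentResult.not_evaluated(test_name, reason=f"{feature} absent")
    col = annotations[feature]
    n_absent = int(col.isna().sum())
    if n_absent:
        logger.info("%s: skipped %d genes with absent annotation", test_name, n_absent)
    positive = set(col.index[col == True])  # noqa: E712 (pandas boolean NA semantics)
    negative = set(col.index[col == False])  # noqa: E712
    if not positive or not negative:
        return EnrichmentResult.not_evaluated(
            test_name, len(positive), len(negative), reason="a class is absent"
        )
    return compare_group_cv(
        stats_table, positive, negative, min_group=min_group, test_name=test_name
    )


def add_bh_fdr(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Attach Benjamini-Hochberg q-values across the evaluated tests."""
    evaluated = [r for r in results if r.evaluated]
    if evaluated:
        _, q, _, _ = multipletests([r.p_value for r in evaluated], method="fdr_bh")
        for r, qv in zip(evaluated, q):
            r.extras["q_value_bh"] = float(qv)
    return results
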