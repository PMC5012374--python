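"""Coefficient-of-variation statistics and quartile-based High-CV classification.

CV is the sample standard deviation (n-1 denominator) divided by the mean of a
gene's FPKM values across cells.  Retained genes are split at the third
quartile of their CV distribution: genes strictly above it are High CV, the
rest Non High CV.  Group comparisons use two-sided Welch t-tests and are only
evaluated when both groups reach a minimum size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .results import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "compute_cv",
    "gene_statistics",
    "CVClassification",
    "classify_quartile",
    "apply_classification",
    "compare_group_cv",
    "gene_type_cv_report",
]

#: minimum genes per group for any CV comparison (below it: not evaluated)
MIN_GROUP = 30


def compute_cv(values) -> float:
    """Sample sd over mean; NaN (undefined) when the mean is not positive."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to compute a CV")
    mean = values.mean()
    if mean <= 0:
        return float("nan")
    return float(values.std(ddof=1) / mean)


def gene_statistics(
    matrix: ExpressionMatrix, retained_ids=None
) -> pd.DataFrame:
    """Per-gene mean, sd, CV, zero count and retention flags as a DataFrame.

    ``retained_ids=None`` marks every gene retained.  Genes with undefined CV
    (zero mean) are counted and excluded from downstream classification.
    """
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, np.nan)
    n_undefined = int(np.isnan(cv).sum())
    if n_undefined:
        logger.info("%d genes have undefined CV (zero mean); excluded downstream", n_undefined)
    retained = (
        np.ones(matrix.n_genes, dtype=bool)
        if retained_ids is None
        else np.array([g in set(retained_ids) for g in matrix.gene_ids])
    )
    return pd.DataFrame(
        {
            "mean_fpkm": means,
            "sd_fpkm": sds,
            "cv": cv,
            "zero_count": matrix.zero_counts(),
            "retained": retained,
            "high_cv": False,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


@dataclass
class CVClassification:
    q3: float  # third quartile of retained-gene CVs
    high_cv_ids: set[str]
    non_high_cv_ids: set[str]


def classify_quartile(stats_table: pd.DataFrame) -> CVClassification:
    """Split retained genes at the third CV quartile; High CV is strictly above.

    The quartile uses linear interpolation between order statistics.  Genes
    with undefined CV are excluded from both the quartile and the classes.
    """
    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    if len(eligible) < 4:
        raise ValueError("need at least 4 retained genes with defined CV")
    q3 = float(np.quantile(eligible["cv"].to_numpy(), 0.75))
    high = set(eligible.index[eligible["cv"] > q3])
    if not high:
        warnings.warn("all CVs tie at the third quartile; High-CV set is empty", stacklevel=2)
    return CVClassification(q3, high, set(eligible.index) - high)


def apply_classification(stats_table: pd.DataFrame, classification: CVClassification) -> pd.DataFrame:
    out = stats_table.copy()
    out["high_cv"] = out.index.isin(classification.high_cv_ids)
    return out


def _direction(mean_a: float, mean_b: float) -> str:
    if mean_a > mean_b:
        return "higher_cv"
    if mean_a < mean_b:
        return "lower_cv"
    return "none"


def compare_group_cv(
    stats_table: pd.DataFrame,
    group_a,
    group_b,
    min_group: int = MIN_GROUP,
    test_name: str = "group_cv",
) -> EnrichmentResult:
    """Two-sided Welch t-test between the CVs of two disjoint gene groups.

    Groups are intersected with retained, CV-defined genes first; a side below
    ``min_group`` makes the result "not evaluated".  The direction reports
    which way group A lies relative to group B.
    """
    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    a = eligible.loc[eligible.index.isin(set(group_a)), "cv"].to_numpy()
    b = eligible.loc[eligible.index.isin(set(group_b)), "cv"].to_numpy()
    if set(group_a) & set(group_b) & set(eligible.index):
        raise ValueError("groups overlap after intersection with retained genes")
    if len(a) < min_group or len(b) < min_group:
        return EnrichmentResult.not_evaluated(
            test_name, len(a), len(b), reason=f"group below {min_group} genes"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(t), float(p)
    if np.isnan(p):
        t, p = 0.0, 1.0
    return EnrichmentResult(
        test_name=test_name,
        statistic=t,
        p_value=p,
        n_a=len(a),
        n_b=len(b),
        effect_direction="none" if t == 0 else _direction(a.mean(), b.mean()),
        extras={"mean_cv_a": float(a.mean()), "mean_cv_b": float(b.mean())},
    )


def gene_type_cv_report(
    stats_table: pd.DataFrame,
    annotations: pd.DataFrame,
    min_group: int = MIN_GROUP,
    reference_type: str = "protein_coding",
) -> list[EnrichmentResult]:
    """Compare each gene type's CVs against protein-coding genes.

    Only types with at least ``min_group`` retained genes are compared (and
    the reference group must reach it too).
    """
    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    types = annotations["gene_type"].reindex(eligible.index)
    ref_genes = set(types.index[types == reference_type])
    if not ref_genes:
        raise ValueError(f"no retained {reference_type} genes to compare against")
    report = []
    for gene_type in sorted(types.dropna().unique()):
        if gene_type == reference_type:
            continue
        group = set(types.index[types == gene_type])
        report.append(
            compare_group_cv(
                stats_table,
                group,
                ref_genes,
                min_group=min_group,
                test_name=f"gene_type:{gene_type}_vs_{reference_type}",
            )
        )
    return report
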