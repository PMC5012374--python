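"""Conservation of expression variability across technologies and species.

CVs computed from two datasets (bulk replicates vs single cells, or mouse vs
human single cells through a one-to-one ortholog map) are compared by Pearson
correlation; orthologous vs species-specific genes by a rank-sum test on
their CVs; and per-gene sequence conservation scores (PhyloP-style, per
5'UTR / exon / 3'UTR) by Pearson correlation against CV plus a decile profile.
Bulk CVs use the same sd/mean definition across replicates as single-cell
CVs across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .results import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "CVComparison",
    "cv_correlation",
    "ortholog_vs_nonortholog_cv",
    "conservation_vs_cv",
]


@dataclass
class CVComparison:
    n_pairs: int
    pearson_r: float
    p_value: float
    shared_high_cv_fraction: float | None = None
    n_dropped: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError(f"Pearson r {self.pearson_r} outside [-1, 1]")
        if self.shared_high_cv_fraction is not None and not (
            0.0 <= self.shared_high_cv_fraction <= 1.0
        ):
            raise ValueError("shared_high_cv_fraction outside [0, 1]")


def cv_correlation(
    cv_a,
    cv_b,
    id_map: dict[str, str] | None = None,
    high_a=None,
    high_b=None,
) -> CVComparison:
    """Pearson correlation of CVs over mapped gene pairs.

    ``id_map`` maps side-A gene ids to side-B ids (identity when None).
    Pairs with an undefined CV on either side are dropped pairwise and
    counted.  When both High-CV sets are supplied, the shared fraction is
    |high_a mapping into high_b| / |high_a with a mapped partner|.
    """
    cv_a = pd.Series(cv_a, dtype=float)
    cv_b = pd.Series(cv_b, dtype=float)
    if id_map is None:
        id_map = {g: g for g in cv_a.index}
    pairs = [
        (a, b)
        for a, b in id_map.items()
        if a in cv_a.index and b in cv_b.index
    ]
    x = np.array([cv_a[a] for a, _ in pairs])
    y = np.array([cv_b[b] for _, b in pairs])
    ok = ~(np.isnan(x) | np.isnan(y))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("cv_correlation: dropped %d pairs with undefined CV", n_dropped)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 mapped pairs with defined CV; got {x.size}")
    r, p = stats.pearsonr(x, y)

    shared = None
    if high_a is not None and high_b is not None:
        high_a, high_b = set(high_a), set(high_b)
        mapped_high_a = {a for a in high_a if a in id_map and id_map[a] in cv_b.index}
        if mapped_high_a:
            shared = len({a for a in mapped_high_a if id_map[a] in high_b}) / len(mapped_high_a)
    return CVComparison(
        n_pairs=int(x.size),
        pearson_r=float(r),
        p_value=float(p),
        shared_high_cv_fraction=shared,
        n_dropped=n_dropped,
    )


def ortholog_vs_nonortholog_cv(
    stats_table: pd.DataFrame, ortholog_map: dict[str, str]
) -> EnrichmentResult:
    """Two-sided rank-sum test: CVs of orthologous vs species-specific genes."""
    test_name = "ortholog_vs_nonortholog_cv"
    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    mapped = eligible.index.isin(set(ortholog_map))
    a = eligible.loc[mapped, "cv"].to_numpy()
    b = eligible.loc[~mapped, "cv"].to_numpy()
    if a.size == 0 or b.size == 0:
        return EnrichmentResult.not_evaluated(
            test_name, int(a.size), int(b.size), reason="a group is empty"
        )
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "none" if med_a == med_b else ("higher_cv" if med_a > med_b else "lower_cv")
    return EnrichmentResult(
        test_name=test_name,
        statistic=float(u),
        p_value=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
        effect_direction=direction,
        extras={"median_cv_orthologs": med_a, "median_cv_specific": med_b},
    )


def conservation_vs_cv(
    stats_table: pd.DataFrame,
    annotations: pd.DataFrame,
    regions=("cons_5utr", "cons_exon", "cons_3utr"),
    n_bins: int = 10,
) -> dict[str, CVComparison]:
    """Per-region Pearson r between sequence conservation score and CV.

    Also reports mean CV per conservation decile for the profile view.
    Regions without scores are skipped with a log line.
    """
    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    out: dict[str, CVComparison] = {}
    for region in regions:
        if region not in annotations.columns or annotations[region].dropna().empty:
            logger.info("conservation_vs_cv: region %s absent, skipped", region)
            continue
        scores = annotations[region].astype(float).reindex(eligible.index)
        ok = scores.notna()
        x = scores[ok].to_numpy(dtype=float)
        y = eligible.loc[ok, "cv"].to_numpy(dtype=float)
        if x.size < 3:
            logger.info("conservation_vs_cv: region %s has <3 scored genes, skipped", region)
            continue
        r, p = stats.pearsonr(x, y)
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        decile_means = [
            float(y[which == b].mean()) if (which == b).any() else float("nan")
            for b in range(n_bins)
        ]
        out[region] = CVComparison(
            n_pairs=int(x.size),
            pearson_r=float(r),
            p_value=float(p),
            extras={"decile_mean_cv": decile_means},
        )
    return out
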