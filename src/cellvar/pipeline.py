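"""End-to-end orchestration: threshold -> CV -> co-expression -> enrichment -> conservation.

Stages communicate only through on-disk artifacts (gene lists and TSV tables)
so each stage can be re-run independently.  A machine-readable manifest
records inputs, parameters, seed, library versions and per-stage outputs;
given the manifest, a run is bit-for-bit reproducible.  Stages whose inputs
are absent are skipped and the skip is logged in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .conservation import conservation_vs_cv, cv_correlation, ortholog_vs_nonortholog_cv
from .coexpression import (
    cluster_cell_specificity,
    extract_clusters,
    neighbour_cooccurrence,
    run_coexpression_test,
    tad_cooccurrence,
)
from .cv_stats import apply_classification, classify_quartile, gene_statistics, gene_type_cv_report
from .enrichment import (
    add_bh_fdr,
    binned_degree_vs_cv,
    bivalency_vs_cv,
    count_factors_per_promoter,
    exclusive_preference_test,
    make_promoters,
    occupancy_vs_cv,
    promoter_class_vs_cv,
)
from .io import (
    read_annotation_table,
    read_bed,
    read_expression_matrix,
    read_ortholog_map,
    write_gene_set,
)
from .noise_threshold import ThresholdConfig, run_noise_threshold
from .results import EnrichmentResult

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_analysis"]

#: standard bin edges for the degree analyses (miRNA targets; interaction partners)
MIRNA_BINS = (50, 100)
PPI_BINS = (1, 2, 3)


@dataclass
class PipelineConfig:
    """All inputs and knobs of a full run; optional inputs may be None."""

    matrix: str
    out_dir: str
    seed: int = 0
    annotations: str | None = None
    peaks_dir: str | None = None
    orthologs: str | None = None
    stats_b: str | None = None  # second per-gene stats TSV (bulk or other species)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    cluster_threshold: float = 0.95
    cluster_linkage: str = "complete"
    n_corr_permutations: int = 100
    n_label_permutations: int = 1000
    min_group: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        threshold = ThresholdConfig(**raw.pop("threshold", {}))
        return cls(threshold=threshold, **raw)


def _results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are available; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": _jsonable(dataclasses.asdict(config)),
        "stages": {},
        "skipped": [],
    }

    matrix = read_expression_matrix(config.matrix)

    # -- stage 1: noise threshold -------------------------------------------
    try:
        threshold_result = run_noise_threshold(matrix, config.threshold)
    except Exception as exc:
        raise RuntimeError(f"stage 'threshold' failed: {exc}") from exc
    write_gene_set(threshold_result.retained_gene_ids, out / "retained_genes.txt")
    window_report = pd.DataFrame(
        [
            {
                "window_index": w.window_index,
                "mean_expr_lo": w.mean_expr_range[0],
                "mean_expr_hi": w.mean_expr_range[1],
                "n_genes": w.n_genes,
                "t_statistic": w.t_statistic,
                "p_value": w.p_value,
                "kept": w.kept,
                "n_dropped_pairs": w.n_dropped_pairs,
            }
            for w in threshold_result.window_results
        ]
    )
    window_report.to_csv(out / "window_report.tsv", sep="\t", index=False)
    with open(out / "threshold.json", "w") as fh:
        json.dump(
            {
                "mean_expression_threshold": threshold_result.mean_expression_threshold,
                "n_retained": len(threshold_result.retained_gene_ids),
                "n_reference": len(threshold_result.reference_gene_ids),
                "n_genes_input": threshold_result.n_genes_input,
                "n_genes_after_zero_filter": threshold_result.n_genes_after_zero_filter,
                "isolated_kept_windows": threshold_result.isolated_kept_windows,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    manifest["stages"]["threshold"] = {
        "threshold": threshold_result.mean_expression_threshold,
        "n_retained": len(threshold_result.retained_gene_ids),
        "outputs": ["retained_genes.txt", "window_report.tsv", "threshold.json"],
    }

    # -- stage 2: CV statistics and High-CV classification -------------------
    try:
        stats_table = gene_statistics(matrix, threshold_result.retained_gene_ids)
        classification = classify_quartile(stats_table)
        stats_table = apply_classification(stats_table, classification)
    except Exception as exc:
        raise RuntimeError(f"stage 'cv' failed: {exc}") from exc
    stats_table.to_csv(out / "gene_stats.tsv", sep="\t", index_label="gene_id")
    write_gene_set(classification.high_cv_ids, out / "high_cv_genes.txt")
    manifest["stages"]["cv"] = {
        "cv_q3": classification.q3,
        "n_high_cv": len(classification.high_cv_ids),
        "outputs": ["gene_stats.tsv", "high_cv_genes.txt"],
    }

    annotations = read_annotation_table(config.annotations) if config.annotations else None

    # -- stage 3: co-expression ----------------------------------------------
    try:
        high_matrix = matrix.subset_genes(sorted(classification.high_cv_ids))
        coexpr = run_coexpression_test(high_matrix, config.n_corr_permutations, config.seed)
        clusters = extract_clusters(
            coexpr.gene_ids, coexpr.corr, config.cluster_threshold, config.cluster_linkage
        )
        specificity = cluster_cell_specificity(matrix, clusters)
    except Exception as exc:
        raise RuntimeError(f"stage 'coexpression' failed: {exc}") from exc
    membership = pd.DataFrame(
        [
            {"cluster_id": c.cluster_id, "gene_id": g, "min_internal_corr": c.min_internal_corr}
            for c in clusters
            for g in sorted(c.gene_ids)
        ]
    )
    membership.to_csv(out / "cluster_members.tsv", sep="\t", index=False)
    specificity.to_csv(out / "cluster_cell_specificity.tsv", sep="\t", index=False)
    location_tests: list[EnrichmentResult] = []
    if annotations is not None:
        location_tests.append(
            tad_cooccurrence(
                annotations, classification.high_cv_ids, config.n_label_permutations, config.seed
            )
        )
        location_tests.append(
            neighbour_cooccurrence(
                annotations, classification.high_cv_ids, config.n_label_permutations, config.seed
            )
        )
    else:
        manifest["skipped"].append("coexpression: TAD/neighbour tests (no annotations)")
    coexpr_report = pd.DataFrame(
        [
            {
                "test_name": "highcv_real_vs_permuted_correlations",
                "statistic": float(np.mean(coexpr.corr[np.triu_indices(len(coexpr.gene_ids), 1)])),
                "p_value": coexpr.wilcoxon_p,
                "n_a": len(coexpr.gene_ids),
                "n_b": int(coexpr.null_corrs.size),
                "effect_direction": "enriched",
                "evaluated": True,
            }
        ]
        + [r.to_dict() for r in location_tests]
    )
    coexpr_report.to_csv(out / "coexpression_report.tsv", sep="\t", index=False)
    manifest["stages"]["coexpression"] = {
        "wilcoxon_p": coexpr.wilcoxon_p,
        "n_clusters": len(clusters),
        "outputs": [
            "cluster_members.tsv",
            "cluster_cell_specificity.tsv",
            "coexpression_report.tsv",
        ],
    }

    # -- stage 4: regulatory enrichment --------------------------------------
    if annotations is not None:
        try:
            enrich_results = _enrichment_stage(
                stats_table, annotations, classification, config, manifest
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc
        _results_frame(add_bh_fdr(enrich_results)).to_csv(
            out / "enrichment_report.tsv", sep="\t", index=False
        )
        manifest["stages"]["enrichment"] = {
            "n_tests": len(enrich_results),
            "outputs": ["enrichment_report.tsv"],
        }
    else:
        manifest["skipped"].append("enrichment (no annotations)")

    # -- stage 5: conservation ------------------------------------------------
    conservation_rows: list[dict] = []
    if annotations is not None:
        try:
            ortho_map = None
            if config.orthologs:
                ortho_map = read_ortholog_map(config.orthologs)
            elif "ortholog_id" in annotations.columns:
                mapped = annotations["ortholog_id"].dropna()
                ortho_map = dict(zip(mapped.index, mapped))
            if ortho_map:
                res = ortholog_vs_nonortholog_cv(stats_table, ortho_map)
                conservation_rows.append(res.to_dict())
            for region, comp in conservation_vs_cv(stats_table, annotations).items():
                conservation_rows.append(
                    {
                        "test_name": f"conservation:{region}",
                        "statistic": comp.pearson_r,
                        "p_value": comp.p_value,
                        "n_a": comp.n_pairs,
                        "n_b": 0,
                        "effect_direction": "lower_cv" if comp.pearson_r < 0 else "higher_cv",
                        "evaluated": True,
                    }
                )
            if config.stats_b:
                other = pd.read_csv(config.stats_b, sep="\t", index_col="gene_id")
                comp = cv_correlation(
                    stats_table.loc[stats_table["retained"], "cv"],
                    other["cv"],
                    id_map=ortho_map,
                )
                conservation_rows.append(
                    {
                        "test_name": "cv_correlation_cross_dataset",
                        "statistic": comp.pearson_r,
                        "p_value": comp.p_value,
                        "n_a": comp.n_pairs,
                        "n_b": comp.n_dropped,
                        "effect_direction": "none",
                        "evaluated": True,
                    }
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'conservation' failed: {exc}") from exc
    if conservation_rows:
        pd.DataFrame(conservation_rows).to_csv(
            out / "conservation_report.tsv", sep="\t", index=False
        )
        manifest["stages"]["conservation"] = {
            "n_tests": len(conservation_rows),
            "outputs": ["conservation_report.tsv"],
        }
    else:
        manifest["skipped"].append("conservation (no annotations or conservation inputs)")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _enrichment_stage(stats_table, annotations, classification, config, manifest) -> list[EnrichmentResult]:
    results: list[EnrichmentResult] = []
    eligible = stats_table[stats_table["retained"] & stats_table["cv"].notna()]
    universe = set(eligible.index)
    high = classification.high_cv_ids & universe
    non_high = classification.non_high_cv_ids & universe

    # ChIP-seq peak files: one BED per factor, factor named by the file stem
    if config.peaks_dir:
        peak_files = sorted(Path(config.peaks_dir).glob("*.bed"))
        if peak_files:
            peak_sets = [read_bed(p) for p in peak_files]
            promoters = make_promoters(annotations)
            counts = count_factors_per_promoter(promoters, peak_sets)
            results.append(occupancy_vs_cv(stats_table, counts, min_group=config.min_group))
            prom_by_gene = {p.gene_id: p for p in promoters}
            for peaks in peak_sets:
                targets = {
                    g
                    for g, c in count_factors_per_promoter(
                        [prom_by_gene[g] for g in sorted(universe) if g in prom_by_gene],
                        [peaks],
                    ).items()
                    if c > 0
                }
                res_high, res_non, exclusive = exclusive_preference_test(
                    targets & universe, high, non_high, universe, test_name=peaks.name
                )
                res_high.extras["exclusive"] = exclusive
                results.extend([res_high, res_non])
        else:
            manifest["skipped"].append("enrichment: factor tests (peaks dir empty)")
    elif "factor_count" in annotations.columns:
        counts = annotations["factor_count"].dropna().astype(int)
        results.append(
            occupancy_vs_cv(stats_table, dict(counts), min_group=config.min_group)
        )
    else:
        manifest["skipped"].append("enrichment: factor occupancy (no peaks, no factor_count)")

    for feature, bins in (("mirna_targets", MIRNA_BINS), ("ppi_degree", PPI_BINS)):
        if feature in annotations.columns:
            degrees = annotations[feature].dropna().astype(int)
            _, tests = binned_degree_vs_cv(
                stats_table, dict(degrees), bins, min_group=config.min_group, test_name=feature
            )
            results.extend(tests)
        else:
            manifest["skipped"].append(f"enrichment: {feature} bins (column absent)")

    t_res, hg_res = bivalency_vs_cv(stats_table, annotations, min_group=config.min_group)
    results.extend([t_res, hg_res])
    for feature in ("cpg_island", "tata"):
        results.append(
            promoter_class_vs_cv(stats_table, annotations, feature, min_group=config.min_group)
        )
    results.extend(gene_type_cv_report(stats_table, annotations, min_group=config.min_group))
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
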