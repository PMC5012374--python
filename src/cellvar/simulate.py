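"""Synthetic single-cell expression data with planted, recoverable ground truth.

The generator emulates the statistical structure the downstream analysis
assumes in real embryonic-stem-cell FPKM matrices:

* per-gene mean expression spread over several orders of magnitude;
* multiplicative technical noise whose log-scale standard deviation
  ``sd_tech(mu) = sqrt(a / mu + b)`` shrinks with the mean, so lowly expressed
  genes are noise-dominated and the CV-vs-mean cloud decreases monotonically;
* logistic dropout: low pre-dropout values are recorded as exact zeros;
* a shared per-cell biological state factor (loading ``bio_sd`` on the log
  scale) that induces positive correlation among well-measured genes — the
  signal the correlation-window threshold procedure detects.  The factor is
  gated off for genes whose technical noise exceeds ``bio_sd``; the mean at
  which ``sd_tech`` crosses ``bio_sd`` is the planted noise boundary;
* gene-intrinsic "shot" noise (bursting noise, variance ``shot_noise / mu``),
  biological but independent across genes, so correlation strength keeps
  rising with the mean even when technical noise is switched off;
* High-CV genes generated as burst genes: a moderate baseline multiplied by
  ``burst_fold`` in a few cells, reproducing the one-cell-dominated signature;
  co-expression modules are groups of burst genes sharing the same burst cells.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical seed and config give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "noise_boundary",
    "simulate_matrix",
    "simulate_annotations",
    "simulate_species_pair",
    "DIRECTION_FEATURES",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic expression model (defaults = study conditions).

    ``mean_log_range`` and ``burst_mean_log_range`` are log10(FPKM) ranges for
    background and burst-gene baseline means.  ``dropout_midpoint`` is the
    log10 expression at which the dropout probability is 0.5 and
    ``dropout_slope`` its steepness per decade; a slope of 0 disables dropout.
    ``bio_sd`` and ``shot_noise`` parameterise the biological components
    described in the module docstring.
    """

    n_genes: int = 10_000
    n_cells: int = 40
    seed: int = 0
    mean_log_range: tuple[float, float] = (0.0, 3.0)
    tech_noise_a: float = 2.0
    tech_noise_b: float = 0.01
    dropout_midpoint: float = 0.0
    dropout_slope: float = 2.0
    bio_sd: float = 0.5
    comp_sd: float = 0.1
    shot_noise: float = 0.5
    n_highcv: int = 150
    burst_cells_per_gene: int = 1
    burst_fold: float = 50.0
    n_modules: int = 3
    module_size: int = 8
    burst_mean_log_range: tuple[float, float] = (2.3, 2.8)
    fraction_orthologs: float = 0.85
    cv_conservation_rho: float = 0.23

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_highcv", "burst_cells_per_gene",
                     "n_modules", "module_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells")
        if self.n_highcv + self.n_modules * self.module_size > self.n_genes:
            raise ValueError("burst and module genes exceed n_genes")
        for name in ("mean_log_range", "burst_mean_log_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        if self.tech_noise_a < 0 or self.tech_noise_b < 0:
            raise ValueError("technical noise parameters must be >= 0")
        if self.bio_sd < 0 or self.shot_noise < 0 or self.comp_sd < 0:
            raise ValueError("bio_sd, comp_sd and shot_noise must be >= 0")
        if self.dropout_slope < 0:
            raise ValueError("dropout_slope must be >= 0 (0 disables dropout)")
        if self.burst_fold <= 1:
            raise ValueError("burst_fold must be > 1")
        if self.burst_cells_per_gene > self.n_cells:
            raise ValueError("burst_cells_per_gene exceeds n_cells")
        if not 0.0 <= self.fraction_orthologs <= 1.0:
            raise ValueError("fraction_orthologs must be in [0, 1]")
        if not -1.0 <= self.cv_conservation_rho <= 1.0:
            raise ValueError("cv_conservation_rho must be in [-1, 1]")


@dataclass
class GroundTruth:
    """What was planted: the oracle every recovery test compares against."""

    true_bio_gene_ids: set[str]
    true_highcv_gene_ids: set[str]
    module_assignments: dict[str, int]
    true_noise_boundary_mean: float  # log(FPKM + 1)
    planted_annotation_directions: dict[str, str] = field(default_factory=dict)


def _sd_tech(mu: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.sqrt(a / mu + b)


def noise_boundary(config: SimulationConfig) -> float:
    """Planted noise boundary in log(FPKM + 1).

    The boundary is the mean at which technical noise sd equals the shared
    biological factor sd; below it the cell-state signal is absent and
    technical variation dominates.  Returns 0 when technical noise never
    reaches ``bio_sd`` (no gene is noise-dominated) and +inf when it always
    exceeds it (no gene carries recoverable signal).
    """
    beta2 = config.bio_sd**2
    if beta2 <= config.tech_noise_b:
        return float("inf")
    if config.tech_noise_a == 0:
        return 0.0
    mu_star = config.tech_noise_a / (beta2 - config.tech_noise_b)
    return float(np.log1p(mu_star))


def _dropout_prob(values: np.ndarray, config: SimulationConfig) -> np.ndarray | None:
    if config.dropout_slope == 0 or not np.isfinite(config.dropout_midpoint):
        return None
    with np.errstate(divide="ignore"):
        log10v = np.log10(np.maximum(values, 1e-300))
    return expit(config.dropout_slope * (config.dropout_midpoint - log10v))


def _render(
    rng: np.random.Generator,
    log10_mu: np.ndarray,
    burst_groups: list[np.ndarray],
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an FPKM matrix from gene means and burst assignments.

    Each entry of ``burst_groups`` is a ``(rows, cells)`` pair: the row
    indices burst together in those cells (singleton row groups give
    independent bursts, larger groups give co-expression modules).
    Returns (values, bio_gene_mask).
    """
    n_genes, n_cells = log10_mu.size, config.n_cells
    mu = 10.0**log10_mu
    sd_tech = _sd_tech(mu, config.tech_noise_a, config.tech_noise_b)
    bio_gene = sd_tech < config.bio_sd  # signal survives only above the noise floor
    h = rng.standard_normal(n_cells)  # shared per-cell biological state
    # Every gene carries a small negative echo of the cell state (-comp_sd):
    # FPKM normalisation is compositional, so cells with globally elevated
    # expression allocate proportionally fewer reads to everything else.
    # Noise-dominated genes therefore anti-correlate slightly with the state.
    loading = config.bio_sd * bio_gene - config.comp_sd
    shot_sd = np.sqrt(config.shot_noise / mu)
    log_x = (
        np.log(mu)[:, None]
        + loading[:, None] * h[None, :]
        + rng.standard_normal((n_genes, n_cells)) * shot_sd[:, None]
        + rng.standard_normal((n_genes, n_cells)) * sd_tech[:, None]
    )
    values = np.exp(log_x)
    for rows, cells, fold in burst_groups:
        values[np.ix_(rows, cells)] *= fold
    p_drop = _dropout_prob(values, config)
    if p_drop is not None:
        values = np.where(rng.random((n_genes, n_cells)) < p_drop, 0.0, values)
    return values, bio_gene


def simulate_matrix(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one expression matrix plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    cell_ids = [f"C{j:02d}" for j in range(config.n_cells)]

    n_module_genes = config.n_modules * config.module_size
    n_burst = config.n_highcv + n_module_genes
    burst_rows = rng.choice(n, size=n_burst, replace=False) if n_burst else np.empty(0, int)
    single_rows = burst_rows[: config.n_highcv]
    module_rows = burst_rows[config.n_highcv:]

    lo, hi = config.mean_log_range
    log10_mu = rng.uniform(lo, hi, size=n)
    if n_burst:
        blo, bhi = config.burst_mean_log_range
        log10_mu[burst_rows] = rng.uniform(blo, bhi, size=n_burst)

    burst_groups = [
        (
            np.array([r]),
            rng.choice(config.n_cells, config.burst_cells_per_gene, replace=False),
            config.burst_fold,
        )
        for r in single_rows
    ]
    # modules burst in disjoint cell sets when possible, so two modules never
    # coincide on the same cell and collapse into one cluster by construction
    module_assignments: dict[str, int] = {}
    if config.n_modules:
        w = config.burst_cells_per_gene
        if config.n_modules * w <= config.n_cells:
            drawn = rng.choice(config.n_cells, config.n_modules * w, replace=False)
            module_cells = [drawn[m * w : (m + 1) * w] for m in range(config.n_modules)]
        else:
            module_cells = [
                rng.choice(config.n_cells, w, replace=False) for _ in range(config.n_modules)
            ]
        for m in range(config.n_modules):
            rows = module_rows[m * config.module_size : (m + 1) * config.module_size]
            burst_groups.append((rows, module_cells[m], config.burst_fold))
            for r in rows:
                module_assignments[gene_ids[r]] = m

    values, bio_gene = _render(rng, log10_mu, burst_groups, config)
    matrix = ExpressionMatrix(gene_ids, cell_ids, values)

    highcv_ids = {gene_ids[r] for r in burst_rows}
    truth = GroundTruth(
        true_bio_gene_ids={gene_ids[i] for i in np.flatnonzero(bio_gene)} | highcv_ids,
        true_highcv_gene_ids=highcv_ids,
        module_assignments=module_assignments,
        true_noise_boundary_mean=noise_boundary(config),
    )
    return matrix, truth


# -- annotation fixtures -------------------------------------------------------

#: features that may carry a planted direction; positional/id features accept
#: only "none" (they are generated without any CV coupling)
DIRECTION_FEATURES = {
    "cpg_island": ("higher_cv", "lower_cv", "none"),
    "tata": ("higher_cv", "lower_cv", "none"),
    "bivalency": ("higher_cv", "lower_cv", "none"),
    "lincrna": ("higher_cv", "lower_cv", "none"),
    "factor_count": ("higher_cv", "lower_cv", "none"),
    "mirna_targets": ("higher_cv", "lower_cv", "none"),
    "ppi_degree": ("higher_cv", "lower_cv", "none"),
    "cons_5utr": ("higher_cv", "lower_cv", "none"),
    "cons_exon": ("higher_cv", "lower_cv", "none"),
    "cons_3utr": ("higher_cv", "lower_cv", "none"),
    "tad_id": ("none",),
    "ortholog_id": ("none",),
}

_COUNT_FEATURES = {  # (negative-binomial mean, gamma shape)
    "factor_count": (10.0, 3.0),
    "mirna_targets": (60.0, 2.0),
    "ppi_degree": (2.5, 2.0),
}


def _cv_percentiles(matrix: ExpressionMatrix) -> np.ndarray:
    """Empirical CV rank percentile per gene, in (0, 1); undefined CVs get 0.5."""
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, np.nan)
    pct = np.full(matrix.n_genes, 0.5)
    ok = ~np.isnan(cv)
    if ok.sum():
        pct[ok] = (rankdata(cv[ok]) - 0.5) / ok.sum()
    return pct


def simulate_annotations(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    directions: dict[str, str],
    seed: int,
    bias: float = 2.5,
    count_bias: float = 1.2,
    cons_noise_sd: float = 0.6,
    n_chromosomes: int = 20,
) -> pd.DataFrame:
    """Generate a per-gene annotation table with planted CV relationships.

    For each feature in ``directions`` with direction ``higher_cv`` or
    ``lower_cv``, membership (or count / score) is sampled with a logistic
    (resp. log-linear / linear) coupling to the gene's empirical CV percentile;
    ``bias`` is the log-odds swing across the CV range.  Features absent from
    ``directions`` are left absent (NA).  Gene positions (chrom, strand, tss)
    are always generated, independent of CV.
    """
    for feature, direction in directions.items():
        if feature not in DIRECTION_FEATURES:
            raise ValueError(f"unknown annotation feature {feature!r}")
        if direction not in DIRECTION_FEATURES[feature]:
            raise ValueError(f"feature {feature!r} does not support direction {direction!r}")

    rng = np.random.default_rng(seed)
    n = matrix.n_genes
    pct = _cv_percentiles(matrix)
    centred = 2.0 * (pct - 0.5)  # in (-1, 1), increasing with CV

    ann = pd.DataFrame(index=pd.Index(matrix.gene_ids, name="gene_id"))
    ann["gene_type"] = "protein_coding"

    # positions: random chromosome, genome order independent of CV
    chroms = np.array([f"chr{c + 1}" for c in rng.integers(0, n_chromosomes, size=n)])
    ann["chrom"] = chroms
    ann["strand"] = np.where(rng.random(n) < 0.5, "+", "-")
    tss = np.zeros(n, dtype=int)
    order = np.lexsort((rng.random(n), chroms))
    for chrom in np.unique(chroms):
        rows = order[chroms[order] == chrom]
        tss[rows] = np.cumsum(rng.integers(10_000, 100_000, size=rows.size)) + 1_000
    ann["tss"] = pd.array(tss, dtype="Int64")

    def sign(direction: str) -> float:
        return {"higher_cv": 1.0, "lower_cv": -1.0, "none": 0.0}[direction]

    for feature in ("cpg_island", "tata"):
        if feature in directions:
            p = expit(sign(directions[feature]) * bias * centred)
            ann[feature] = pd.array(rng.random(n) < p, dtype="boolean")

    if "lincrna" in directions:
        p = expit(logit(0.12) + sign(directions["lincrna"]) * bias * centred)
        ann.loc[rng.random(n) < p, "gene_type"] = "lincRNA"

    if "bivalency" in directions:
        s = sign(directions["bivalency"])
        w_biv = np.exp(s * bias * centred / 2.0)
        w_act = np.exp(-s * bias * centred / 2.0)
        w = np.stack([w_biv, w_act, np.ones(n)], axis=1)
        w /= w.sum(axis=1, keepdims=True)
        draw = rng.random(n)
        choice = (draw[:, None] > np.cumsum(w, axis=1)).sum(axis=1)
        ann["bivalency"] = np.array(["bivalent", "active", "other"])[choice]

    for feature, (mean, shape) in _COUNT_FEATURES.items():
        if feature in directions:
            lam = rng.gamma(shape, mean / shape, size=n)
            lam *= np.exp(sign(directions[feature]) * count_bias * centred)
            ann[feature] = pd.array(rng.poisson(lam), dtype="Int64")

    for feature in ("cons_5utr", "cons_exon", "cons_3utr"):
        if feature in directions:
            # "lower_cv" means conserved genes have low CV: score decreases with CV
            score = sign(directions[feature]) * centred + rng.normal(0.0, cons_noise_sd, size=n)
            ann[feature] = pd.array(score, dtype="Float64")

    if "tad_id" in directions:
        tad = np.empty(n, dtype=object)
        tad_counter = 0
        for chrom in np.unique(chroms):
            rows = np.flatnonzero(chroms == chrom)
            rows = rows[np.argsort(tss[rows])]
            i = 0
            while i < rows.size:
                size = int(rng.integers(5, 16))
                for r in rows[i : i + size]:
                    tad[r] = f"tad{tad_counter:04d}"
                tad_counter += 1
                i += size
        ann["tad_id"] = tad

    if "ortholog_id" in directions:
        mapped = rng.random(n) < 0.85
        ortho = np.where(mapped, [f"ORTH{i:05d}" for i in range(n)], None)
        ann["ortholog_id"] = ortho

    truth.planted_annotation_directions.update(directions)
    return ann


# -- cross-species pairs -------------------------------------------------------


def simulate_species_pair(
    config: SimulationConfig, seed: int
) -> tuple[
    tuple[ExpressionMatrix, pd.DataFrame],
    tuple[ExpressionMatrix, pd.DataFrame],
    dict[str, str],
]:
    """Generate two species' matrices whose ortholog CVs share latent drivers.

    A per-ortholog latent score with cross-species correlation
    ``cv_conservation_rho`` drives both the gene mean (hence the mean-dependent
    part of the CV) and burst membership (genes in the top mean percentile
    burst, so their high CV survives the zero filter).  Non-ortholog genes get
    independent latents.  Returns ``(matrix, annotations)`` per species plus
    the one-to-one ortholog map (species A id -> species B id).
    """
    rng = np.random.default_rng(seed)
    n = config.n_genes
    rho = config.cv_conservation_rho
    n_orth = int(round(config.fraction_orthologs * n))

    z_a = rng.standard_normal(n)
    z_b = rho * z_a + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    z_b[n_orth:] = rng.standard_normal(n - n_orth)  # species-specific genes

    lo, hi = config.mean_log_range
    p_burst = (config.n_highcv + config.n_modules * config.module_size) / max(n, 1)

    out = []
    for prefix, z in (("A", z_a), ("B", z_b)):
        u = norm.cdf(z)
        log10_mu = lo + (hi - lo) * u
        # graded burst propensity: intensity ramps over the top latent tail, so
        # ortholog pairs share a continuous CV driver rather than a binary one
        ramp = 4.0 * p_burst
        intensity = np.clip((u - (1.0 - ramp)) / ramp, 0.0, 1.0) if p_burst else np.zeros_like(u)
        burst_rows = np.flatnonzero(intensity > 0)
        burst_groups = [
            (
                np.array([r]),
                rng.choice(config.n_cells, config.burst_cells_per_gene, replace=False),
                float(config.burst_fold ** intensity[r]),
            )
            for r in burst_rows
        ]
        values, _ = _render(rng, log10_mu, burst_groups, config)
        gene_ids = [f"{prefix}_G{i:05d}" for i in range(n)]
        cell_ids = [f"{prefix}_C{j:02d}" for j in range(config.n_cells)]
        matrix = ExpressionMatrix(gene_ids, cell_ids, values)
        ann = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
        ann["gene_type"] = "protein_coding"
        out.append((matrix, ann))

    (mat_a, ann_a), (mat_b, ann_b) = out
    ortholog_map = {mat_a.gene_ids[i]: mat_b.gene_ids[i] for i in range(n_orth)}
    ann_a["ortholog_id"] = [ortholog_map.get(g) for g in mat_a.gene_ids]
    ann_b["ortholog_id"] = [mat_a.gene_ids[i] if i < n_orth else None for i in range(n)]
    return (mat_a, ann_a), (mat_b, ann_b), ortholog_map
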