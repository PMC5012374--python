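# Methods

## The analysis

`cellvar` treats a genes × cells FPKM matrix as a mixture of biological
cell-to-cell variation and expression-dependent technical noise, and asks
four questions: where does biology start to dominate (noise threshold), which
genes are unusually variable (CV quartile), do the variable genes co-vary
(co-expression), and is variability structured by regulation and conserved
across species.

### Noise threshold

The procedure assumes that well-measured genes share cell-level variation
with the most highly expressed genes, while noise-dominated genes do not.
Genes with ≥ `max_zero_cells` zeros are discarded (default: 90% of cells,
i.e. 36 of 40). Genes strictly above `ref_min_fpkm` (default 150 FPKM) in
*every* cell form the reference set. Remaining genes are sorted by mean FPKM
and cut into windows of `window_size` (default 1000) genes; the remainder is
pooled into the lowest window, so it may be oversized. All window × reference
Pearson correlations (raw FPKM across cells; a flag switches to
log(FPKM+1)) are pooled per window and compared with the lowest window by a
one-sided Welch t-test (H1: shifted right), at `alpha` = 0.05 without
multiple-testing correction by default (Bonferroni available by flag).

Retention is window-level: the retained set is the maximal contiguous run of
significant windows ending at the highest-mean window, plus the reference
genes (biological by construction). The threshold is the smallest
log(FPKM+1) gene mean in that run. Two conventions close the corner cases:
an isolated significant window below the run is logged but not retained (a
single reported threshold implies contiguity), and when *every* tested
window is significant the untested lowest window is retained too — if no
window looks like noise, there is no evidence for a noise floor anywhere.
When nothing is significant the threshold is +∞ and only the references are
retained.

The pooled t-test treats correlation values as independent although they
share the same cells, so it is strongly anticonservative for tiny shifts;
the procedure is reliable because the real decision margin is the jump in
mean correlation at the noise boundary, which is orders of magnitude larger
than the between-window drift. This is a property of the method being
reproduced, not of the implementation.

### CV classification

CV uses the sample (n−1) standard deviation over the mean — with ~40 cells
the estimator convention is material. Genes with zero mean have undefined CV
and are excluded with a report (absent is not zero). Q3 is the 75th
percentile of retained-gene CVs with linear interpolation between order
statistics; High CV means strictly above Q3, so heavy ties shrink the High
set. Group comparisons are two-sided Welch t-tests, evaluated only when both
groups have ≥ 30 genes after intersection with retained, CV-defined genes.

### Co-expression

Pairwise Pearson correlations on raw FPKM. The null permutes each gene's
values across cells independently (preserving per-gene marginals, destroying
cell structure) and pools all pairwise correlations; real vs null is a
two-sided Wilcoxon rank-sum. Clusters come from hierarchical clustering on
1 − r cut at 1 − 0.95; complete linkage is the default because it converts
the cut into a guarantee (`min_internal_corr ≥ 0.95` for every reported
cluster); average linkage is available. TAD co-occurrence (number of TADs
holding ≥ 2 High-CV genes) and neighbour co-occurrence (adjacent
same-chromosome pairs both High CV) use label-permutation nulls with the
add-one estimator p = (1 + #{null ≥ observed})/(n_perm + 1), so p ∈
(1/(n+1), 1].

### Enrichment

Promoters are TSS ± 1 kb in 0-based half-open coordinates, identical on both
strands, clipped at zero. Factor occupancy counts *distinct* factors with
≥ 1 overlapping peak (half-open overlap; touching ≠ overlapping), so
splitting a peak in two changes nothing. The occupancy contrast excludes
genes at exactly the cut (10), since the comparison is "fewer than" vs "more
than". Factor preference is the upper-tail hypergeometric probability of the
observed High-CV overlap; "exclusive" preference additionally requires no
enrichment among Non-High-CV genes, and both sub-tests are always reported.
Degree features are binned with inclusive upper edges (miRNA: 1–50, 51–100,
>100; PPI: 1, 2, 3, >3; degree 0 excluded) with Welch tests between adjacent
bins. Bivalency is tested both as a CV difference (bivalent vs active,
Welch) and as a set overlap with High CV over the retained universe
(hypergeometric) — the study this reimplements reports both framings.
Benjamini–Hochberg q-values are attached across a battery alongside raw p.

### Conservation

Cross-dataset CV agreement is a Pearson correlation over mapped pairs
(identity map, or a strictly one-to-one ortholog map), dropping pairs with
undefined CV on either side. Bulk CVs use the same sd/mean definition across
replicates. The shared-High-CV fraction is |High_A mapping into High_B| /
|High_A with a mapped partner|. Orthologous vs species-specific CVs are
compared with a two-sided rank-sum test. Sequence conservation is a
per-region Pearson correlation of score vs CV plus mean CV per conservation
decile.

## The synthetic-data generator

The generator is the package's study system: it emulates the statistical
structure the analysis assumes, with planted, recoverable truth.

For gene g with true mean μ_g (log10 μ uniform on `mean_log_range`,
default (0, 3)) and cell c:

    log x_gc = log μ_g + λ_g·h_c + shot_gc + tech_gc
    λ_g = bio_sd·1[sd_tech(μ_g) < bio_sd] − comp_sd

* `h_c ~ N(0,1)` is a shared cell-state factor. Genes whose technical noise
  exceeds `bio_sd` (default 0.5) carry none of it — the mean μ* where
  `sd_tech(μ*) = bio_sd` is the **planted noise boundary**, reported as
  log(μ*+1). This hard gate is a sharpening of reality (real signal decays
  smoothly); it is what makes the boundary a well-defined recoverable
  parameter.
* `comp_sd` (default 0.1) is a small negative loading on h for *every*
  gene: FPKM normalisation is compositional, so cells with globally elevated
  expression allocate proportionally fewer reads to everything else.
  Noise-dominated genes therefore anti-correlate slightly with the
  reference genes, as in normalised data, keeping below-boundary windows
  from drifting above the baseline by chance.
* `tech_gc ~ N(0, a/μ + b)` with a = 2, b = 0.01: mean-dependent technical
  noise, the source of the decreasing CV-vs-mean cloud.
* `shot_gc ~ N(0, shot_noise/μ)` (default 0.5) is gene-intrinsic bursting
  noise — biological, independent across genes — so correlation with the
  references keeps increasing with the mean even when technical noise is
  switched off (the noise-free limit then retains everything, as it should).
* **Dropout**: each value is zeroed with probability
  logistic(slope·(midpoint − log10 x)), slope 2 per decade, midpoint at
  1 FPKM; slope 0 disables it. Dropout acts on the *value*, not the gene
  mean, so a burst in one cell is captured even for a modest baseline.
* **High-CV genes** are burst genes: baseline log10 μ uniform on
  (2.3, 2.8), multiplied by `burst_fold` (50) in `burst_cells_per_gene` (1)
  random cells. The baseline sits high enough that spike heights are
  measured with little noise — pairwise correlation between genes sharing a
  burst cell saturates at exp(−σ²_independent), so tight r > 0.95 modules
  require σ ≲ 0.15 at the burst baseline. Modules share their burst cells;
  module cell sets are drawn disjointly so two modules never merge by cell
  collision. Single-burst genes may share cells by chance, which produces
  additional small one-cell-dominated clusters — the same signature the
  co-expression stage looks for.
* **Annotations** are sampled against the empirical CV rank percentile:
  logistic membership for boolean features, softmax for bivalency classes,
  Gamma–Poisson counts with a log-linear CV coupling for occupancy/miRNA/PPI
  (negative binomial spread is needed to populate the outer bins), linear
  score plus Gaussian noise for conservation. The direction map is recorded
  in the ground truth; features not requested stay absent. Positions, TADs
  and ortholog ids are generated independent of CV.
* **Species pairs** share a latent bivariate-normal score with correlation
  `cv_conservation_rho` per ortholog pair; the score drives the gene mean
  (hence the mean-dependent part of CV) and a *graded* burst propensity
  (fold = burst_fold^t with t ramping over the top latent tail), so ortholog
  CVs share a continuous driver. Non-orthologs get independent scores.
  Recovered cross-species r is computed on threshold-passing genes, as the
  ortholog analysis prescribes; r ≈ 0.65 at ρ = 0.9 — attenuation comes from
  CV-estimation noise at 40 cells and the nonlinearity of the mean→CV map.

Determinism: one seeded `numpy.random.Generator` per simulation call, fixed
draw order; identical config + seed ⇒ bit-identical output, and the pipeline
manifest (inputs, parameters, seed, versions) suffices to re-run
byte-identically.

What the generator does *not* emulate: UMI/count statistics, batch and
library-size effects beyond the single compositional echo, cell-cycle
structure, multi-factor biological states, smooth (rather than gated) decay
of signal with expression, and read-level processing. Passing tests show the
procedures recover what they are designed to recover under this model — not
that the thresholds found on real data are correct.

## Problem sizes and numerical choices

Default study conditions are 10,000 genes × 40 cells for threshold recovery
(window 1000), 2,000 genes for the module-recovery and classification
checks (window 200), 1,200–1,500 genes for the enrichment calibration
batteries, and 3,000 genes per species for the conservation grid; the
narrative drivers under `analysis/` use 6,000 genes with 600-gene windows so
the co-expression stage (≈1,100 High-CV genes, pooled permutation null)
stays comfortably in memory. Correlations are clipped to [−1, 1]; the
correlation matrix is symmetrised before clustering; undefined correlations
(constant vectors) are dropped and counted everywhere; Welch tests that
receive two constant equal samples report p = 1 rather than NaN; permutation
p-values use the add-one rule. Quantiles are linear-interpolated order
statistics; switching the quantile rule or linkage is a one-argument change.

## Known limitations

* The window t-test's anticonservativeness (shared-cell dependence) is
  inherited from the method; a cluster-robust or gene-level test would be
  the statistical fix but would no longer be the same procedure.
* Gene-level retention ("keep the genes with significantly higher
  correlation") is ambiguous in the source method; window-level retention is
  implemented because the method reports a single expression threshold.
* The hypergeometric universe for set-overlap tests is the retained gene
  set; other choices (all genes, all annotated genes) change p-values.
* With 40 cells, CV estimates are noisy (relative s.e. ≈ 15–20%); all
  downstream contrasts inherit that noise floor.
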