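# cellvar

Gene-expression variability analysis for single-cell RNA-seq, built around the
coefficient of variation (CV = sd/mean of a gene's FPKM across single cells).

Single-cell FPKM matrices mix genuine cell-to-cell biology with heavy
technical noise (amplification bias, dropout), and the noise is worst for
lowly expressed genes. `cellvar` implements a correlation-window procedure to
find the expression level above which biological variation dominates, then
characterises the genes on either side of the CV spectrum:

1. **Noise threshold** — discard genes with too many zeros; take genes above
   150 FPKM in *every* cell as a confident reference set; sort the rest by
   mean expression into windows of 1000 genes; Pearson-correlate every window
   gene with every reference gene across cells; Welch-t-test each window's
   correlation distribution against the lowest (noise) window, one-sided for
   a right shift; retain the contiguous run of significant windows from the
   top. The threshold is the low edge of that run in log(FPKM + 1).
2. **CV classes** — among retained genes, the *High CV* set is the fourth
   quartile of the CV distribution (strictly above Q3).
3. **Co-expression** — pairwise correlations of High-CV genes against a
   within-gene permutation null (Wilcoxon rank-sum); hierarchical clustering
   on 1 − r cut at r > 0.95 (complete linkage, so the cut is a guarantee on
   the minimum within-cluster correlation); per-cluster cell-dominance
   profiles; TAD and gene-neighbourhood label-permutation tests.
4. **Regulatory correlates** — promoter (TSS ± 1 kb) factor occupancy
   (< 10 vs > 10 factors), hypergeometric binding preference per factor,
   miRNA-target bins (1–50 / 51–100 / > 100), protein-interaction bins
   (1 / 2 / 3 / > 3), bivalent-vs-active chromatin, CpG/TATA promoter class.
5. **Conservation** — cross-dataset and cross-species Pearson correlation of
   CVs through one-to-one ortholog maps; orthologous vs species-specific CV
   distributions; sequence-conservation scores (per 5′UTR / exon / 3′UTR)
   against CV.

Real accession-scale inputs are out of scope here; instead a first-class
synthetic-data generator (`cellvar.simulate`) plants every signal the
analysis is supposed to find — a noise boundary, burst-driven High-CV genes,
co-expression modules sharing burst cells, annotation biases with known
direction, and a tunable cross-species CV conservation — so each stage is
tested against known ground truth. See `docs/methods.md` for the generative
model and its limits.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
with planted ground truth:

```sh
python analysis/01_simulate_data.py --seed 1   # writes results/data/
python analysis/02_noise_threshold.py
python analysis/03_cv_classification.py
python analysis/04_regulation_enrichment.py
python analysis/05_coexpression.py --seed 1
python analysis/06_conservation.py --seed 1
```

With seed 1 this prints (abridged):

```
recovered threshold: 1.968 log(FPKM+1); planted boundary 2.234
retained genes: 4534 of 6000
CV third quartile (retained genes): 0.722
High-CV genes: 1134 of 4534 retained
median CV by expression tercile (retained genes):
low 0.754   mid 0.559   high 0.525
  occupancy_gt10_vs_lt10   p= 1.87e-94 lower_cv   SIGNIFICANT
  bivalent_vs_active_cv    p= 9.65e-55 higher_cv  SIGNIFICANT
  cpg_island_vs_cv         p= 5.69e-72 lower_cv   SIGNIFICANT
  tata_vs_cv               p=   0.0198 lower_cv   quiet
High-CV genes: 1134; real-vs-permuted Wilcoxon p = 0
  cluster 10: 12 genes (8 planted), top cell C05, dominance 38.5x
cross-species CV correlation: rho 0.0 -> r = -0.028 ... rho 0.9 -> r = 0.667
sequence conservation cons_exon: r = -0.429 (negative coupling planted)
```

Reading it: the window procedure localises the planted noise boundary to
within one window's span; the CV cloud declines with expression; the planted
regulatory biases (CpG → stable, bivalent → variable, occupancy
anti-correlated with CV) come out significant with the right sign while the
unplanted ones (TATA, miRNA, PPI) stay quiet; each planted module resurfaces
as one r > 0.95 cluster whose expression is dominated by a single cell; and
recovered cross-species CV correlation tracks the planted conservation
strength.

A `cellvar` CLI mirrors the stages (`simulate`, `threshold`, `cv`,
`coexpress`, `enrich`, `conserve`, `run-all`); `run-all` executes everything
from a YAML config and writes a manifest sufficient to re-run bit-identically.

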