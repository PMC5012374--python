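"""Generate the synthetic study data: expression matrix, annotations, truth.

Produces a gene x cell FPKM matrix with mean-dependent technical noise,
dropout, a shared cell-state factor, burst-driven High-CV genes and three
co-expression modules, plus an annotation table with planted CV relationships
(CpG islands on stable genes, bivalency on variable genes, factor occupancy
anti-correlated with CV).  Everything downstream analyses consume lives under
results/data/.
"""

import argparse
import json
from pathlib import Path

from cellvar.io import write_annotation_table, write_expression_matrix, write_ortholog_map
from cellvar.simulate import SimulationConfig, simulate_annotations, simulate_matrix

DIRECTIONS = {
    "cpg_island": "lower_cv",
    "tata": "none",
    "bivalency": "higher_cv",
    "factor_count": "lower_cv",
    "mirna_targets": "none",
    "ppi_degree": "none",
    "cons_5utr": "lower_cv",
    "cons_exon": "lower_cv",
    "cons_3utr": "lower_cv",
    "tad_id": "none",
    "ortholog_id": "none",
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-genes", type=int, default=6000)
    parser.add_argument("--out", default="results/data")
    args = parser.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(n_genes=args.n_genes, seed=args.seed)
    matrix, truth = simulate_matrix(config)
    annotations = simulate_annotations(matrix, truth, DIRECTIONS, seed=args.seed + 1)

    write_expression_matrix(matrix, out / "matrix.tsv")
    write_annotation_table(annotations, out / "annotations.tsv")
    mapped = annotations["ortholog_id"].dropna()
    write_ortholog_map(dict(zip(mapped.index, mapped)), out / "orthologs.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "true_noise_boundary_mean": truth.true_noise_boundary_mean,
                "true_highcv_gene_ids": sorted(truth.true_highcv_gene_ids),
                "module_assignments": truth.module_assignments,
                "planted_annotation_directions": truth.planted_annotation_directions,
                "n_true_bio_genes": len(truth.true_bio_gene_ids),
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    n_zero = float((matrix.values == 0).mean())
    print(f"simulated {config.n_genes} genes x {config.n_cells} cells (seed {args.seed})")
    print(f"  planted noise boundary: {truth.true_noise_boundary_mean:.3f} log(FPKM+1)")
    print(f"  planted High-CV genes: {len(truth.true_highcv_gene_ids)} "
          f"({config.n_modules} modules of {config.module_size})")
    print(f"  dropout zeros: {100 * n_zero:.1f}% of entries")
    print(f"  wrote matrix/annotations/orthologs/truth under {out}/")


if __name__ == "__main__":
    main()
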