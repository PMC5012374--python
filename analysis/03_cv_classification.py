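"""Classify retained genes by CV: the High-CV set is the fourth quartile.

Computes per-gene CV (sample sd over mean across cells), takes the third
quartile over retained genes and flags genes strictly above it as High CV.
Also compares CVs per gene type against protein-coding genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from cellvar.cv_stats import (
    apply_classification,
    classify_quartile,
    gene_statistics,
    gene_type_cv_report,
)
from cellvar.io import read_annotation_table, read_expression_matrix, read_gene_set, write_gene_set


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", default="results/data")
    parser.add_argument("--out", default="results")
    args = parser.parse_args()

    out = Path(args.out)
    matrix = read_expression_matrix(Path(args.data) / "matrix.tsv")
    retained = set(read_gene_set(out / "retained_genes.txt"))
    annotations = read_annotation_table(Path(args.data) / "annotations.tsv")

    stats = gene_statistics(matrix, retained)
    classification = classify_quartile(stats)
    stats = apply_classification(stats, classification)
    stats.to_csv(out / "gene_stats.tsv", sep="\t", index_label="gene_id")
    write_gene_set(classification.high_cv_ids, out / "high_cv_genes.txt")

    retained_stats = stats[stats["retained"]]
    print(f"CV third quartile (retained genes): {classification.q3:.3f}")
    print(f"High-CV genes: {len(classification.high_cv_ids)} of {len(retained_stats)} retained")
    print("median CV by expression tercile (retained genes):")
    terciles = pd.qcut(retained_stats["mean_fpkm"], 3, labels=["low", "mid", "high"])
    print(retained_stats.groupby(terciles, observed=True)["cv"].median().round(3).to_string())

    report = gene_type_cv_report(stats, annotations)
    for r in report:
        flag = f"p={r.p_value:.2e} ({r.effect_direction})" if r.evaluated else "not evaluated"
        print(f"  {r.test_name}: {flag}")


if __name__ == "__main__":
    main()
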