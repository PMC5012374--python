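"""Readers and writers for every on-disk representation the pipeline touches.

All genomic intervals use BED-native 0-based half-open coordinates, everywhere.
Two intervals (s1, e1) and (s2, e2) overlap iff ``s1 < e2 and s2 < e1``;
touching intervals do not overlap.  Inputs in 1-based coordinates must be
converted by the caller (``read_bed(..., one_based=True)`` shifts starts).

Missing per-gene annotation values are *absent* (NA), never 0: a gene with no
recorded factor binding and a gene known to be bound by zero factors are
different facts, and every consumer of an annotation column skips absent genes
and reports how many were skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "IntervalSet",
    "intervals_overlap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_bed",
    "write_bed",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gene_set",
    "write_gene_set",
    "read_annotation_table",
    "write_annotation_table",
    "ANNOTATION_COLUMNS",
]


@dataclass
class ExpressionMatrix:
    """A gene x cell matrix of non-negative FPKM values.

    Invariants enforced at construction: unique gene and cell identifiers,
    no negative values, at least two cells.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(self.cell_ids) < 2:
            raise ValueError("an expression matrix needs at least 2 cells")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if np.isnan(self.values).any():
            g, c = map(int, np.argwhere(np.isnan(self.values))[0])
            raise ValueError(
                f"missing value for gene {self.gene_ids[g]!r} / cell {self.cell_ids[c]!r}"
            )
        if (self.values < 0).any():
            g, c = map(int, np.argwhere(self.values < 0)[0])
            raise ValueError(
                f"negative value {self.values[g, c]} for gene "
                f"{self.gene_ids[g]!r} in cell {self.cell_ids[c]!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index()[gene_id]]

    def gene_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def zero_counts(self) -> np.ndarray:
        return (self.values == 0).sum(axis=1)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.cell_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class IntervalSet:
    """A named set of 0-based half-open genomic intervals (e.g. one factor's peaks)."""

    name: str
    intervals: list[tuple[str, int, int]]
    labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0:
                raise ValueError(f"negative coordinate in {self.name}: {chrom}:{start}-{end}")
            if start >= end:
                raise ValueError(f"empty or inverted interval in {self.name}: {chrom}:{start}-{end}")
        if self.labels is not None and len(self.labels) != len(self.intervals):
            raise ValueError("labels must match intervals one-to-one")

    def __len__(self) -> int:
        return len(self.intervals)


def intervals_overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    """Half-open overlap test; touching intervals do not overlap."""
    return s1 < e2 and s2 < e1


# -- expression matrices -------------------------------------------------------


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a tab-separated genes x cells FPKM matrix.

    First column holds gene ids, the header row holds cell ids.  Duplicate
    ids, negative values and ragged rows are rejected with the offending
    identifier or line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cells = header[1:]
    dup = _first_duplicate(cells)
    if dup is not None:
        raise ValueError(f"duplicate cell id in {path.name}: {dup!r}")
    n_fields = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise ValueError(
                    f"ragged row at line {lineno} of {path.name}: "
                    f"expected {n_fields} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"non-numeric value at line {lineno} of {path.name}") from exc
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ValueError(f"duplicate gene id in {path.name}: {dup!r}")
    values = np.asarray(rows, dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        g, c = map(int, neg[0])
        raise ValueError(
            f"negative value for gene {gene_ids[g]!r} in cell {cells[c]!r} of {path.name}"
        )
    return ExpressionMatrix(gene_ids, cells, values)


def _first_duplicate(items) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# -- BED intervals -------------------------------------------------------------


def read_bed(path, name: str | None = None, one_based: bool = False) -> IntervalSet:
    """Read BED3+ intervals, preserving order; optional 4th column is the label.

    ``one_based=True`` converts inclusive 1-based starts to the internal
    0-based half-open convention.
    """
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    labels: list[str] = []
    any_label = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno} of {path.name}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if one_based:
                start -= 1
            if start >= end:
                raise ValueError(
                    f"line {lineno} of {path.name}: start >= end ({start} >= {end})"
                )
            if start < 0:
                raise ValueError(f"line {lineno} of {path.name}: negative start {start}")
            intervals.append((chrom, start, end))
            if len(parts) >= 4 and parts[3] != "":
                labels.append(parts[3])
                any_label = True
            else:
                labels.append("")
    return IntervalSet(
        name=name or path.stem,
        intervals=intervals,
        labels=labels if any_label else None,
    )


def write_bed(interval_set: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(interval_set.intervals):
            if interval_set.labels is not None:
                fh.write(f"{chrom}\t{start}\t{end}\t{interval_set.labels[i]}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


# -- ortholog maps and gene sets ----------------------------------------------


def read_ortholog_map(path) -> dict[str, str]:
    """Read a two-column TSV of one-to-one orthologs into a bijective mapping."""
    mapping: dict[str, str] = {}
    values: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            a, b = parts
            if a in mapping:
                raise ValueError(f"gene {a!r} mapped twice; orthology must be one-to-one")
            if b in values:
                raise ValueError(f"gene {b!r} mapped twice; orthology must be one-to-one")
            mapping[a] = b
            values.add(b)
    return mapping


def write_ortholog_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for a in sorted(mapping):
            fh.write(f"{a}\t{mapping[a]}\n")


def read_gene_set(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


# -- annotation tables ---------------------------------------------------------

#: fixed column vocabulary of the per-gene annotation table (gene_id is the index)
ANNOTATION_COLUMNS = [
    "gene_type",
    "chrom",
    "strand",
    "tss",
    "cpg_island",
    "tata",
    "bivalency",
    "factor_count",
    "mirna_targets",
    "ppi_degree",
    "tad_id",
    "ortholog_id",
    "cons_5utr",
    "cons_exon",
    "cons_3utr",
]

_BOOL_COLS = ("cpg_island", "tata")
_INT_COLS = ("tss", "factor_count", "mirna_targets", "ppi_degree")
_FLOAT_COLS = ("cons_5utr", "cons_exon", "cons_3utr")


def read_annotation_table(path) -> pd.DataFrame:
    """Read a per-gene annotation TSV (fixed header, gene_id first).

    Empty fields are NA ("absent"), never coerced to 0 or False.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "gene_id":
        raise ValueError("annotation table must start with a gene_id column")
    unknown = [c for c in df.columns[1:] if c not in ANNOTATION_COLUMNS]
    if unknown:
        raise ValueError(f"unknown annotation columns: {unknown}")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in annotation table: {dup!r}")
    df = df.replace("", pd.NA)
    for col in df.columns:
        if col in _BOOL_COLS:
            bad = set(df[col].dropna()) - {"True", "False"}
            if bad:
                raise ValueError(f"column {col}: non-boolean values {sorted(bad)}")
            df[col] = df[col].map({"True": True, "False": False}).astype("boolean")
        elif col in _INT_COLS:
            df[col] = df[col].astype("Int64")
        elif col in _FLOAT_COLS:
            df[col] = df[col].astype("Float64")
    return df


def write_annotation_table(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    for col in out.columns:
        if col in _BOOL_COLS:
            out[col] = out[col].map({True: "True", False: "False"})
    out.to_csv(path, sep="\t", index_label="gene_id", na_rep="")
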