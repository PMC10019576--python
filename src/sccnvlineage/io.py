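"""Core containers and plain-text readers/writers.

The pipeline exchanges three families of artifacts:

* 10x-style count matrices — a Matrix Market triplet file plus
  ``genes.tsv`` / ``barcodes.tsv``, or a single dense TSV with genes as
  rows and cell barcodes as columns;
* a gene annotation TSV mapping each gene to a chromosome label and a
  base-pair start position that is used purely as an ordering key;
* TSV reports produced by the designation stage, one row per cell plus
  a per-cell-type summary of malignant / non-malignant counts.

Gene and cell order is preserved exactly as found in the files.
Chromosome-position ordering is applied only inside the CNV-inference
stage, so downstream results are invariant to input gene order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Valid per-cell designations in a report.
DESIGNATIONS = ("malignant", "non-malignant")

#: Cell-type vocabulary used throughout the pipeline.
CELL_TYPES = ("malignant-candidate", "EC", "mural", "T", "TAM", "OLG", "unknown")

ANNOTATION_COLUMNS = ("gene_id", "chromosome", "start_bp")
METADATA_COLUMNS = ("cell_id", "cell_type", "is_reference", "sample_id")


class FormatError(ValueError):
    """An input file or in-memory table violates the expected format."""


def _check_unique(names: Sequence, what: str, source: str | Path | None = None) -> None:
    s = pd.Series(list(names))
    dup = s[s.duplicated()].unique()
    if len(dup):
        where = f" in {source}" if source is not None else ""
        shown = ", ".join(map(str, dup[:10]))
        raise FormatError(f"duplicate {what}{where}: {shown}")


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells, in file order.

    Entries are validated to be non-negative integers; the matrix is
    stored sparse (CSR) regardless of how it was supplied.
    """

    genes: list
    cells: list
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.cells = [str(c) for c in self.cells]
        _check_unique(self.genes, "gene_id")
        _check_unique(self.cells, "cell barcode")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"count matrix shape {m.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if m.nnz:
            coo = m.tocoo()
            bad = np.flatnonzero(coo.data < 0)
            if bad.size:
                i = bad[0]
                raise FormatError(
                    f"negative count at gene row {coo.row[i] + 1}, "
                    f"cell column {coo.col[i] + 1}: {coo.data[i]}"
                )
            rounded = np.round(coo.data)
            bad = np.flatnonzero(coo.data != rounded)
            if bad.size:
                i = bad[0]
                raise FormatError(
                    f"non-integer count at gene row {coo.row[i] + 1}, "
                    f"cell column {coo.col[i] + 1}: {coo.data[i]}"
                )
        self.counts = m.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the cells selected by a boolean mask."""
        keep = np.asarray(keep, dtype=bool)
        cells = [c for c, k in zip(self.cells, keep) if k]
        return CountMatrix(self.genes, cells, self.counts[:, keep])

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep, dtype=bool)
        genes = [g for g, k in zip(self.genes, keep) if k]
        return CountMatrix(genes, self.cells, self.counts[keep, :])


def read_counts(matrix_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style triplet matrix with its gene and barcode tables.

    The Matrix Market body uses 1-based indices; file order of genes and
    cells is preserved.
    """
    matrix_path, genes_path, barcodes_path = (
        Path(matrix_path), Path(genes_path), Path(barcodes_path),
    )
    for p in (matrix_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        m = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on malformed files
        raise FormatError(f"{matrix_path}: invalid Matrix Market file: {exc}") from exc
    genes_tbl = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    barcodes_tbl = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    genes = genes_tbl.iloc[:, 0].tolist()
    cells = barcodes_tbl.iloc[:, 0].tolist()
    _check_unique(genes, "gene_id", genes_path)
    if m.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{matrix_path}: declared shape {m.shape} does not match "
            f"{len(genes)} genes / {len(cells)} barcodes"
        )
    return CountMatrix(genes, cells, sp.csr_matrix(m))


def write_counts(cm: CountMatrix, outdir) -> dict[str, Path]:
    """Write a CountMatrix as matrix.mtx + genes.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), cm.counts.tocoo(), field="integer")
    pd.DataFrame({"gene_id": cm.genes, "name": cm.genes}).to_csv(
        paths["genes"], sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": cm.cells}).to_csv(
        paths["barcodes"], sep="\t", header=False, index=False
    )
    return paths


def read_counts_dense(path) -> CountMatrix:
    """Read a dense TSV count matrix (genes as rows, barcodes as header)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.dtype.kind not in "iuf":
        raise FormatError(f"{path}: non-numeric entries in count matrix")
    return CountMatrix(df.index.tolist(), df.columns.tolist(), sp.csr_matrix(values))


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene_id, chromosome, start_bp).

    Returns a DataFrame in file order; chromosome order elsewhere in the
    pipeline is the order of first appearance in this table.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; header must contain "
                          f"{list(ANNOTATION_COLUMNS)}")
    start = pd.to_numeric(df["start_bp"], errors="coerce")
    bad = np.flatnonzero(start.isna().to_numpy())
    if bad.size:
        # +2: one for the header line, one for 1-based line numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise FormatError(f"{path}: non-numeric start_bp at line(s) {lines}")
    if (start < 0).any():
        i = int(np.flatnonzero((start < 0).to_numpy())[0])
        raise FormatError(f"{path}: negative start_bp at line {i + 2}")
    _check_unique(df["gene_id"], "gene_id", path)
    out = df.loc[:, ["gene_id", "chromosome"]].copy()
    out["start_bp"] = start.astype(np.int64)
    return out


def make_gene_annotation(gene_ids, chromosomes, starts) -> pd.DataFrame:
    """Assemble and validate an annotation table from parallel sequences."""
    df = pd.DataFrame({
        "gene_id": [str(g) for g in gene_ids],
        "chromosome": [str(c) for c in chromosomes],
        "start_bp": np.asarray(starts, dtype=np.int64),
    })
    _check_unique(df["gene_id"], "gene_id")
    if (df["start_bp"] < 0).any():
        raise FormatError("negative start_bp in annotation")
    return df


def write_gene_annotation(annotation: pd.DataFrame, path) -> Path:
    path = Path(path)
    annotation.to_csv(path, sep="\t", index=False)
    return path


def make_cell_metadata(cell_ids, cell_types, reference_types=("T",),
                       sample_id="sample") -> pd.DataFrame:
    """Build a cell metadata table; ``is_reference`` follows the reference types."""
    types = [str(t) for t in cell_types]
    unknown = sorted(set(types) - set(CELL_TYPES))
    if unknown:
        raise FormatError(f"unknown cell_type label(s): {unknown}")
    ref = set(reference_types)
    df = pd.DataFrame({
        "cell_id": [str(c) for c in cell_ids],
        "cell_type": types,
        "is_reference": [t in ref for t in types],
        "sample_id": str(sample_id),
    })
    _check_unique(df["cell_id"], "cell_id")
    return df


def read_cell_metadata(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cell_type": str,
                                            "sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if df["is_reference"].dtype != bool:
        df["is_reference"] = (
            df["is_reference"].astype(str).str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if df["is_reference"].isna().any():
            raise FormatError(f"{path}: is_reference must be boolean")
    _check_unique(df["cell_id"], "cell_id", path)
    return df


def write_cell_metadata(meta: pd.DataFrame, path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class DesignationReport:
    """Per-cell malignant / non-malignant calls with summary tabulations.

    ``cells`` has one row per cell (cell_id, cell_type, cnv_signal,
    cnv_signal_signature, best_group, best_correlation,
    correlation_defined, designation).  ``type_summary`` mirrors the
    aneuploid/diploid per-cell-type tabulation style of copyKAT-type
    reports.  ``cluster_fractions`` is present only when transcriptome
    cluster labels were supplied with the metadata.
    """

    cells: pd.DataFrame
    type_summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    cluster_fractions: pd.DataFrame | None = None
    signal_threshold: float | None = None
    correlation_threshold: float | None = None

    def __post_init__(self) -> None:
        required = {"cell_id", "cell_type", "cnv_signal", "best_correlation",
                    "designation"}
        missing = required - set(self.cells.columns)
        if missing:
            raise FormatError(f"report missing columns: {sorted(missing)}")
        bad = set(self.cells["designation"]) - set(DESIGNATIONS)
        if bad:
            raise FormatError(f"invalid designation label(s): {sorted(bad)}")
        _check_unique(self.cells["cell_id"], "cell_id")
        if self.type_summary is None:
            self.type_summary = summarize_designations(self.cells)
        # conservation: per-type counts must sum to the number of cells
        total = int(self.type_summary[["n_malignant", "n_non_malignant"]].to_numpy().sum())
        if total != len(self.cells):
            raise FormatError(
                f"type summary accounts for {total} cells, report has {len(self.cells)}"
            )


def summarize_designations(cells: pd.DataFrame) -> pd.DataFrame:
    """Tabulate malignant / non-malignant counts per cell type."""
    if len(cells) == 0:
        return pd.DataFrame(columns=["cell_type", "n_malignant", "n_non_malignant"])
    tab = (
        cells.groupby(["cell_type", "designation"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(DESIGNATIONS), fill_value=0)
        .reset_index()
    )
    tab.columns = ["cell_type", "n_malignant", "n_non_malignant"]
    return tab


def write_report(report: DesignationReport, outdir) -> dict[str, Path]:
    """Write the per-cell report and the per-type summary as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"cells": outdir / "cells.tsv", "summary": outdir / "summary.tsv"}
    report.cells.to_csv(paths["cells"], sep="\t", index=False)
    report.type_summary.to_csv(paths["summary"], sep="\t", index=False)
    if report.cluster_fractions is not None:
        paths["clusters"] = outdir / "clusters.tsv"
        report.cluster_fractions.to_csv(paths["clusters"], sep="\t", index=False)
    return paths


def read_report_cells(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cell_type": str,
                                              "designation": str})
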