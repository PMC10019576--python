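"""Expression-based CNV inference.

Raw counts are turned into per-cell inferred copy-number profiles by
the inferCNV-style chain:

1. QC: drop cells with excessive mitochondrial or hemoglobin (red
   blood cell) count fractions;
2. log-normalize each cell to a fixed total (``scale_total``, default
   10,000), log base 2 so values read as dosage ratios;
3. center each gene on the mean over a set of reference cells assumed
   karyotypically normal (T cells in the mouse setting; T cells, TAMs
   and OLGs in the human setting), then cap extreme values at +/- cap
   to bound single-gene leverage;
4. sort genes by chromosome and position and smooth each cell's
   centered values with a moving average over a window of genes
   (default 101, the odd-width counterpart of a 100-gene window);
   windows shrink at chromosome edges and never cross a chromosome
   boundary;
5. optionally subtract each cell's median smoothed value, removing
   residual per-cell technical offsets so diploid cells center at 0.

The result is a :class:`CNVMatrix`: 0 is diploid-like, positive values
gain-like, negative values loss-like.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, FormatError

logger = logging.getLogger(__name__)


class InferenceError(RuntimeError):
    """A CNV-inference stage could not run on its input."""


@dataclass
class SmoothingParams:
    """Tunable parameters of the CNV-inference chain.

    window_genes must be odd so the moving-average window is symmetric
    around its center gene.  cap bounds the absolute centered
    log-expression before smoothing.  min_mean_expr (mean normalized
    expression across cells) can exclude near-silent genes; the default
    0 keeps every gene.
    """

    window_genes: int = 101
    cap: float = 3.0
    recenter_cells: bool = True
    log_base: float = 2.0
    scale_total: float = 10_000.0
    min_reference_cells: int = 20
    min_mean_expr: float = 0.0
    max_mito_frac: float = 0.05
    max_rbc_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.window_genes < 1 or self.window_genes % 2 == 0:
            raise ValueError("window_genes must be a positive odd integer")
        if self.cap <= 0:
            raise ValueError("cap must be positive")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if self.scale_total <= 0:
            raise ValueError("scale_total must be positive")


@dataclass
class CNVMatrix:
    """Per-gene, per-cell inferred CNV deviations.

    Genes are strictly sorted by (chromosome order, start_bp, gene_id);
    chrom_bounds maps each chromosome to its half-open row range
    [lo, hi) in that order.
    """

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    chrom_bounds: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("CNV value matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite CNV values")
        covered = sum(hi - lo for lo, hi in self.chrom_bounds.values())
        if covered != len(self.genes):
            raise ValueError("chromosome bounds do not cover the gene axis")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_bounds)

    def gene_chromosomes(self) -> np.ndarray:
        out = np.empty(len(self.genes), dtype=object)
        for chrom, (lo, hi) in self.chrom_bounds.items():
            out[lo:hi] = chrom
        return out

    def chromosome_mask(self, chromosomes) -> np.ndarray:
        """Boolean gene mask for a chromosome set ("all" selects every gene)."""
        if isinstance(chromosomes, str):
            if chromosomes == "all":
                return np.ones(len(self.genes), dtype=bool)
            chromosomes = [chromosomes]
        mask = np.zeros(len(self.genes), dtype=bool)
        for chrom in chromosomes:
            if chrom not in self.chrom_bounds:
                raise KeyError(f"unknown chromosome {chrom!r}")
            lo, hi = self.chrom_bounds[chrom]
            mask[lo:hi] = True
        return mask

    def cell_index(self, cell_ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cells)}
        try:
            return np.asarray([pos[c] for c in cell_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"cell {exc.args[0]!r} not in CNV matrix") from None

    def to_frame(self) -> pd.DataFrame:
        chroms = self.gene_chromosomes()
        df = pd.DataFrame(self.values, columns=self.cells)
        df.insert(0, "chromosome", chroms)
        df.insert(0, "gene_id", self.genes)
        return df


def write_cnv_matrix(cnv: CNVMatrix, path) -> None:
    """Write the full CNV matrix as TSV (genes in chromosome order)."""
    cnv.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cnv_matrix(path) -> CNVMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    genes = df["gene_id"].tolist()
    chroms = df["chromosome"].to_numpy()
    values = df.drop(columns=["gene_id", "chromosome"]).to_numpy(dtype=float)
    bounds: dict[str, tuple[int, int]] = {}
    i = 0
    while i < len(chroms):
        j = i
        while j < len(chroms) and chroms[j] == chroms[i]:
            j += 1
        if chroms[i] in bounds:
            raise FormatError(f"chromosome {chroms[i]!r} rows are not contiguous")
        bounds[str(chroms[i])] = (i, j)
        i = j
    cells = [c for c in df.columns if c not in ("gene_id", "chromosome")]
    return CNVMatrix(genes, cells, values, bounds)


# ---------------------------------------------------------------------------
# QC and normalization


def _genes_by_prefix(genes: Sequence[str], prefixes: tuple[str, ...]) -> list[str]:
    low = [p.lower() for p in prefixes]
    return [g for g in genes if str(g).lower().startswith(tuple(low))]


def qc_filter_cells(counts: CountMatrix,
                    mito_genes: Sequence[str] | None = None,
                    hb_genes: Sequence[str] | None = None,
                    max_mito_frac: float = 0.05,
                    max_rbc_frac: float = 0.05) -> CountMatrix:
    """Drop cells with high mitochondrial or red-blood-cell fractions.

    Cells are removed when their mitochondrial count fraction exceeds
    ``max_mito_frac`` or their hemoglobin count fraction reaches
    ``max_rbc_frac`` (the "red blood cells <5%" retention rule).  Gene
    sets default to prefix matching: ``mt-`` for mitochondrial genes,
    ``Hba``/``Hbb`` for hemoglobins.
    """
    if mito_genes is None:
        mito_genes = _genes_by_prefix(counts.genes, ("mt-",))
    if hb_genes is None:
        hb_genes = _genes_by_prefix(counts.genes, ("hba", "hbb"))
    idx = {g: i for i, g in enumerate(counts.genes)}
    mito_rows = [idx[g] for g in mito_genes if g in idx]
    hb_rows = [idx[g] for g in hb_genes if g in idx]

    total = np.asarray(counts.counts.sum(axis=0)).ravel().astype(float)
    total[total == 0] = np.nan  # zero-library cells fail normalization later
    mito_frac = (np.asarray(counts.counts[mito_rows, :].sum(axis=0)).ravel() / total
                 if mito_rows else np.zeros(counts.n_cells))
    hb_frac = (np.asarray(counts.counts[hb_rows, :].sum(axis=0)).ravel() / total
               if hb_rows else np.zeros(counts.n_cells))
    keep = ~((mito_frac > max_mito_frac) | (hb_frac >= max_rbc_frac))
    keep = np.where(np.isnan(mito_frac) | np.isnan(hb_frac), True, keep)
    n_removed = int((~keep).sum())
    logger.info("QC: removed %d of %d cells (mito > %.3g or RBC >= %.3g)",
                n_removed, counts.n_cells, max_mito_frac, max_rbc_frac)
    if not keep.any():
        raise InferenceError("no cells survive QC")
    if n_removed == 0:
        return counts
    return counts.subset_cells(keep)


def normalize_log(counts: CountMatrix, params: SmoothingParams) -> np.ndarray:
    """Library-normalized log expression.

    value[g, c] = log_base(1 + count[g, c] * scale_total / libsize[c]).
    """
    libsize = np.asarray(counts.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = ", ".join(counts.cells[i] for i in zero[:10])
        raise InferenceError(f"zero library size for cell(s): {names}")
    scaled = counts.counts.multiply(params.scale_total / libsize[None, :]).tocsr()
    out = np.asarray(scaled.todense(), dtype=float)
    np.log1p(out, out=out)
    out /= np.log(params.log_base)
    return out


def center_on_reference(norm: np.ndarray, is_reference: np.ndarray,
                        cell_ids: Sequence[str],
                        params: SmoothingParams) -> np.ndarray:
    """Subtract the reference-cell mean per gene, then cap at +/- cap.

    The reference mean is accumulated over reference columns sorted by
    cell id, so the result is bitwise independent of input cell order.
    """
    is_reference = np.asarray(is_reference, dtype=bool)
    n_ref = int(is_reference.sum())
    if n_ref < params.min_reference_cells:
        raise InferenceError(
            f"only {n_ref} reference cells; at least "
            f"{params.min_reference_cells} required"
        )
    ref_idx = np.flatnonzero(is_reference)
    order = np.argsort(np.asarray(cell_ids, dtype=object)[ref_idx].astype(str),
                       kind="stable")
    ref_mean = norm[:, ref_idx[order]].mean(axis=1)
    centered = norm - ref_mean[:, None]
    np.clip(centered, -params.cap, params.cap, out=centered)
    return centered


# ---------------------------------------------------------------------------
# Smoothing


def sort_genes_by_position(genes: Sequence[str], annotation: pd.DataFrame,
                           chrom_order: Sequence[str] | None = None
                           ) -> tuple[np.ndarray, dict[str, tuple[int, int]], list[str]]:
    """Order genes by (chromosome, start_bp, gene_id).

    Chromosome order is the order of first appearance in the annotation
    unless ``chrom_order`` overrides it.  Returns the permutation of the
    input gene axis, the half-open chromosome bounds in the sorted
    order, and the sorted gene list.
    """
    ann = annotation.set_index("gene_id")
    missing = [g for g in genes if g not in ann.index]
    if missing:
        raise InferenceError(
            f"{len(missing)} gene(s) missing from annotation, e.g. {missing[:5]}"
        )
    chroms = ann.loc[list(genes), "chromosome"].to_numpy()
    starts = ann.loc[list(genes), "start_bp"].to_numpy()
    if chrom_order is None:
        chrom_order = list(dict.fromkeys(annotation["chromosome"]))
    rank = {c: i for i, c in enumerate(chrom_order)}
    unknown = set(chroms) - set(rank)
    if unknown:
        raise InferenceError(f"chromosome(s) not in declared order: {sorted(unknown)}")
    keys = np.array([(rank[c], s, g) for c, s, g in zip(chroms, starts, genes)],
                    dtype=[("rank", int), ("start", int), ("gene", object)])
    perm = np.argsort(keys, order=("rank", "start", "gene"), kind="stable")
    sorted_chroms = chroms[perm]
    bounds: dict[str, tuple[int, int]] = {}
    i = 0
    while i < len(sorted_chroms):
        j = i
        while j < len(sorted_chroms) and sorted_chroms[j] == sorted_chroms[i]:
            j += 1
        bounds[str(sorted_chroms[i])] = (i, j)
        i = j
    for chrom in chrom_order:
        if chrom not in bounds:
            warnings.warn(f"chromosome {chrom!r} has no annotated genes; skipped")
    sorted_genes = [genes[i] for i in perm]
    return perm, bounds, sorted_genes


def _windowed_mean(block: np.ndarray, window: int) -> np.ndarray:
    """Moving average along axis 0 with shrink-at-edge windows."""
    if window == 1:
        return block.astype(float, copy=True)
    n = block.shape[0]
    half = (window - 1) // 2
    cs = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)[:, None]


def smooth_moving_average(centered: np.ndarray, genes: Sequence[str],
                          annotation: pd.DataFrame, params: SmoothingParams,
                          chrom_order: Sequence[str] | None = None,
                          cells: Sequence[str] | None = None) -> CNVMatrix:
    """Chromosome-bounded moving average of centered expression.

    Each gene's value becomes the mean of the centered values over the
    window of ``window_genes`` genes centered on it, intersected with
    its own chromosome: windows shrink near chromosome edges and never
    cross a boundary.  Chromosomes with fewer genes than the window are
    averaged over their full span.
    """
    centered = np.asarray(centered, dtype=float)
    if centered.shape[0] != len(genes):
        raise ValueError("centered matrix rows do not match gene list")
    perm, bounds, sorted_genes = sort_genes_by_position(genes, annotation, chrom_order)
    ordered = centered[perm, :]
    smoothed = np.empty_like(ordered)
    for chrom, (lo, hi) in bounds.items():
        smoothed[lo:hi] = _windowed_mean(ordered[lo:hi], params.window_genes)
    if cells is None:
        cells = [f"cell{i}" for i in range(centered.shape[1])]
    return CNVMatrix(sorted_genes, list(cells), smoothed, bounds)


def recenter_per_cell(cnv: CNVMatrix) -> CNVMatrix:
    """Subtract each cell's median CNV value from its profile."""
    med = np.median(cnv.values, axis=0)
    return CNVMatrix(cnv.genes, cnv.cells, cnv.values - med[None, :],
                     dict(cnv.chrom_bounds))


# ---------------------------------------------------------------------------
# Full chain


def infer_cnv(counts: CountMatrix, annotation: pd.DataFrame, meta: pd.DataFrame,
              params: SmoothingParams | None = None,
              mito_genes: Sequence[str] | None = None,
              hb_genes: Sequence[str] | None = None,
              apply_qc: bool = True,
              chrom_order: Sequence[str] | None = None) -> CNVMatrix:
    """Run QC -> normalize -> center -> smooth -> recenter.

    ``meta`` must contain every cell of ``counts`` (extra rows are
    ignored); its ``is_reference`` column defines the diploid baseline.
    Genes absent from the annotation are dropped with a logged count.
    """
    params = params or SmoothingParams()
    if apply_qc:
        counts = qc_filter_cells(counts, mito_genes, hb_genes,
                                 params.max_mito_frac, params.max_rbc_frac)
    ann_genes = set(annotation["gene_id"])
    keep = np.asarray([g in ann_genes for g in counts.genes])
    if not keep.all():
        logger.info("dropping %d gene(s) absent from annotation", int((~keep).sum()))
        counts = counts.subset_genes(keep)
    meta = meta.set_index("cell_id")
    missing = [c for c in counts.cells if c not in meta.index]
    if missing:
        raise InferenceError(f"{len(missing)} cell(s) missing from metadata, "
                             f"e.g. {missing[:5]}")
    is_ref = meta.loc[counts.cells, "is_reference"].to_numpy(dtype=bool)

    norm = normalize_log(counts, params)
    if params.min_mean_expr > 0:
        keep = norm.mean(axis=1) >= params.min_mean_expr
        logger.info("dropping %d gene(s) below min mean expression",
                    int((~keep).sum()))
        norm = norm[keep]
        counts = counts.subset_genes(keep)
    centered = center_on_reference(norm, is_ref, counts.cells, params)
    cnv = smooth_moving_average(centered, counts.genes, annotation, params,
                                chrom_order=chrom_order, cells=counts.cells)
    if params.recenter_cells:
        cnv = recenter_per_cell(cnv)
    return cnv
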