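"""Marker-panel cell-type annotation.

Stromal cell types in the glioblastoma microenvironment are labeled
from small panels of lineage markers: endothelial cells (ECs), mural
cells (pericytes / vascular smooth muscle), T lymphocytes,
tumor-associated microglia/macrophages (TAMs) and oligodendrocytes
(OLGs).  A cell's score for a type is the mean log-normalized
expression of that type's panel genes; a cell is labeled with the
top-scoring type only when the top score clears an absolute floor and
beats the runner-up by a margin.  Cells that fail either rule remain
"malignant-candidate" and feed the CNV-clustering stage, mirroring the
practice of clustering everything that is not a confidently-annotated
stromal type.

Scoring is intentionally a transparent mean over panel genes rather
than a rank-based module score; it is adequate for well-separated
panels and for the bundled simulator, and its limitation on shallow
real data is documented in the methods note.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import make_cell_metadata

logger = logging.getLogger(__name__)

#: Mouse marker panels (gene symbols in mouse casing).
DEFAULT_MOUSE_PANEL: dict[str, tuple[str, ...]] = {
    "EC": ("Pecam1", "Tek", "Cldn5"),
    "mural": ("Kcnj8", "Pdgfrb", "Acta2", "Tbx18"),
    "T": ("Cd2", "Cd3d", "Cd3e", "Cd3g"),
    "TAM": ("Cd14", "Tmem119", "Aif1"),
    "OLG": ("Cldn11", "Mag", "Mbp", "Klk6"),
}

#: Human panels: same genes, upper-case symbols.
DEFAULT_HUMAN_PANEL: dict[str, tuple[str, ...]] = {
    t: tuple(g.upper() for g in genes) for t, genes in DEFAULT_MOUSE_PANEL.items()
}

SPECIES_PANELS = {"mouse": DEFAULT_MOUSE_PANEL, "human": DEFAULT_HUMAN_PANEL}

#: Default reference cell types for the two study settings.
MOUSE_REFERENCE_TYPES = ("T",)
HUMAN_REFERENCE_TYPES = ("T", "TAM", "OLG")


def validate_panel(panel: Mapping[str, Sequence[str]]) -> None:
    """Panels must be non-empty and pairwise disjoint."""
    seen: dict[str, str] = {}
    for cell_type, genes in panel.items():
        if not genes:
            raise ValueError(f"empty marker panel for {cell_type!r}")
        for g in genes:
            if g in seen:
                raise ValueError(
                    f"marker {g!r} assigned to both {seen[g]!r} and {cell_type!r}"
                )
            seen[g] = cell_type


def score_markers(norm, genes: Sequence[str],
                  panel: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Mean normalized expression of each panel across cells.

    Parameters
    ----------
    norm
        Log-normalized expression, genes x cells (dense or sparse).
    genes
        Gene identifiers for the rows of ``norm``.
    panel
        Mapping cell type -> marker gene ids.  Panel genes absent from
        ``genes`` are excluded from the mean; a panel with no present
        genes is omitted with a warning.

    Returns
    -------
    DataFrame of shape cells x types.
    """
    validate_panel(panel)
    index = {g: i for i, g in enumerate(genes)}
    if sp.issparse(norm):
        norm = np.asarray(norm.todense())
    scores: dict[str, np.ndarray] = {}
    for cell_type, markers in panel.items():
        rows = [index[g] for g in markers if g in index]
        absent = [g for g in markers if g not in index]
        if absent:
            logger.info("panel %s: %d marker(s) absent from data: %s",
                        cell_type, len(absent), absent)
        if not rows:
            warnings.warn(
                f"marker panel {cell_type!r} has no genes present; type omitted"
            )
            continue
        scores[cell_type] = np.asarray(norm[rows, :]).mean(axis=0)
    return pd.DataFrame(scores)


def assign_types(scores: pd.DataFrame, cell_ids: Sequence[str],
                 min_score: float = 0.25, margin: float = 0.1,
                 reference_types: Sequence[str] = MOUSE_REFERENCE_TYPES,
                 sample_id: str = "sample") -> pd.DataFrame:
    """Turn panel scores into cell-type labels.

    A cell is labeled argmax-type when the top score is at least
    ``min_score`` and exceeds the second-best score by at least
    ``margin``; otherwise it stays "malignant-candidate" and is treated
    as a candidate tumor cell downstream.  Ties at the top never clear
    the margin, so tied cells remain candidates.
    """
    if scores.shape[1] == 0:
        labels = ["malignant-candidate"] * len(cell_ids)
        return make_cell_metadata(cell_ids, labels, reference_types, sample_id)
    vals = scores.to_numpy()
    order = np.argsort(vals, axis=1)
    top_idx = order[:, -1]
    top = vals[np.arange(len(vals)), top_idx]
    second = vals[np.arange(len(vals)), order[:, -2]] if vals.shape[1] > 1 \
        else np.zeros(len(vals))
    types = scores.columns.to_numpy()
    labels = np.where((top >= min_score) & (top - second >= margin),
                      types[top_idx], "malignant-candidate")
    return make_cell_metadata(cell_ids, labels.tolist(), reference_types, sample_id)


def annotate_cells(norm, genes: Sequence[str], cell_ids: Sequence[str],
                   panel: Mapping[str, Sequence[str]] | None = None,
                   min_score: float = 0.25, margin: float = 0.1,
                   reference_types: Sequence[str] = MOUSE_REFERENCE_TYPES,
                   sample_id: str = "sample") -> pd.DataFrame:
    """Score panels and assign labels in one call."""
    panel = DEFAULT_MOUSE_PANEL if panel is None else panel
    scores = score_markers(norm, genes, panel)
    return assign_types(scores, cell_ids, min_score=min_score, margin=margin,
                        reference_types=reference_types, sample_id=sample_id)
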