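"""Clonal grouping and the two CNA-based per-cell measures.

Candidate tumor cells are grouped into clones by hierarchical
clustering (Ward linkage on Euclidean distances between per-cell CNV
profiles).  Each group carries a mean CNV profile and a set of
"signature" chromosomes — the chromosomes where the group shows a
concordant dosage shift.  Two per-cell statistics are then computed:

* CNV signal — the mean of squared CNV values over a chromosome set
  (genome-wide, or a group's signature), measuring overall aneuploidy;
* CNV correlation — the Pearson correlation between a cell's CNV
  profile restricted to a group's signature chromosomes and the
  group's mean profile on the same genes.

A cell is designated malignant when, for its best-correlated group,
both its signature CNV signal and its correlation exceed thresholds
calibrated as upper quantiles of the same statistics over the
reference (assumed-diploid) cells.  Cells whose correlations are all
undefined (constant profiles) are non-malignant by construction.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .infer import CNVMatrix
from .io import DesignationReport

logger = logging.getLogger(__name__)


class CorrelationResult(NamedTuple):
    """A Pearson correlation that may be undefined (constant input)."""

    value: float
    defined: bool


@dataclass
class CNVGroup:
    """A hierarchically derived clone of candidate malignant cells."""

    group_id: str
    cells: list[str]
    mean_profile: np.ndarray
    signature_chromosomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("empty CNV group")
        if not self.signature_chromosomes:
            raise ValueError(f"group {self.group_id}: empty signature chromosome set")


@dataclass
class ClassificationThresholds:
    """Reference-quantile calibration of the malignancy rule.

    A cell is malignant iff its signature CNV signal exceeds the
    ``signal_quantile`` of the reference cells' signals AND its best
    correlation exceeds the ``correlation_quantile`` of the reference
    cells' best correlations.
    """

    signal_quantile: float = 0.95
    correlation_quantile: float = 0.95

    def __post_init__(self) -> None:
        for q in (self.signal_quantile, self.correlation_quantile):
            if not 0 < q < 1:
                raise ValueError("quantiles must lie in (0, 1)")


def _group_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def select_signature_chromosomes(mean_profile: np.ndarray,
                                 chrom_bounds: Mapping[str, tuple[int, int]],
                                 min_effect: float = 0.05,
                                 override: Sequence[str] | None = None
                                 ) -> tuple[str, ...]:
    """Chromosomes with a concordant dosage shift in a group mean profile.

    Selects every chromosome whose mean CNV value has absolute value
    above ``min_effect``; if none qualifies, falls back to the single
    chromosome with the largest absolute mean.  ``override`` (e.g. a
    published per-sample chromosome list) is returned verbatim.
    """
    if override is not None:
        override = tuple(str(c) for c in override)
        unknown = set(override) - set(chrom_bounds)
        if unknown:
            raise KeyError(f"override names unknown chromosome(s): {sorted(unknown)}")
        return override
    means = {c: float(np.mean(mean_profile[lo:hi]))
             for c, (lo, hi) in chrom_bounds.items() if hi > lo}
    selected = tuple(c for c, m in means.items() if abs(m) > min_effect)
    if selected:
        return selected
    best = max(means, key=lambda c: abs(means[c]))
    return (best,)


def cluster_cnv_groups(cnv: CNVMatrix, candidate_cells: Sequence[str], k: int,
                       min_group_size: int = 20, min_effect: float = 0.05,
                       signature_overrides: Mapping[str, Sequence[str]] | None = None,
                       linkage_method: str = "ward") -> list[CNVGroup]:
    """Cut a Ward dendrogram of candidate-cell CNV profiles into k groups.

    Groups are labeled A, B, ... in decreasing size (ties broken by the
    lexicographically smallest member cell id) and carry mean profiles
    and signature chromosomes.  Groups smaller than ``min_group_size``
    are dropped with a warning — tiny cuts are noise, not clones.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    candidate_cells = [str(c) for c in candidate_cells]
    if k > len(candidate_cells):
        raise ValueError(f"k={k} exceeds the {len(candidate_cells)} candidate cells")
    idx = cnv.cell_index(candidate_cells)
    X = cnv.values[:, idx].T
    if len(candidate_cells) == 1:
        labels = np.ones(1, dtype=int)
    else:
        Z = linkage(X, method=linkage_method)
        labels = fcluster(Z, t=k, criterion="maxclust")
    members: dict[int, list[str]] = {}
    for cell, lab in zip(candidate_cells, labels):
        members.setdefault(int(lab), []).append(cell)
    ordered = sorted(members.values(), key=lambda cells: (-len(cells), min(cells)))
    kept = [cells for cells in ordered if len(cells) >= min_group_size]
    dropped = len(ordered) - len(kept)
    if dropped:
        warnings.warn(f"dropped {dropped} group(s) below min size {min_group_size}")
    groups: list[CNVGroup] = []
    overrides = signature_overrides or {}
    for label, cells in zip(_group_labels(len(kept)), kept):
        cols = cnv.cell_index(sorted(cells))  # sorted: order-invariant mean
        profile = cnv.values[:, cols].mean(axis=1)
        signature = select_signature_chromosomes(
            profile, cnv.chrom_bounds, min_effect, overrides.get(label))
        groups.append(CNVGroup(label, cells, profile, signature))
    return groups


def cnv_signal(profile: np.ndarray, chromosomes,
               chrom_bounds: Mapping[str, tuple[int, int]] | None = None,
               mask: np.ndarray | None = None) -> float:
    """Mean of squared CNV values over a chromosome set.

    ``chromosomes`` may be "all" (genome-wide), a label, or an iterable
    of labels; a precomputed boolean gene ``mask`` may be given instead
    of bounds.
    """
    profile = np.asarray(profile, dtype=float)
    if mask is None:
        mask = _chromosome_mask(len(profile), chromosomes, chrom_bounds)
    if not mask.any():
        raise ValueError("chromosome selection maps to zero genes")
    sel = profile[mask]
    return float(np.mean(sel * sel))


def _chromosome_mask(n_genes: int, chromosomes,
                     chrom_bounds: Mapping[str, tuple[int, int]] | None) -> np.ndarray:
    if isinstance(chromosomes, str) and chromosomes == "all":
        return np.ones(n_genes, dtype=bool)
    if chrom_bounds is None:
        raise ValueError("chrom_bounds required for a chromosome subset")
    if isinstance(chromosomes, str):
        chromosomes = [chromosomes]
    mask = np.zeros(n_genes, dtype=bool)
    for chrom in chromosomes:
        if chrom not in chrom_bounds:
            raise KeyError(f"unknown chromosome {chrom!r}")
        lo, hi = chrom_bounds[chrom]
        mask[lo:hi] = True
    return mask


def cnv_correlation(profile: np.ndarray, group: CNVGroup,
                    chrom_bounds: Mapping[str, tuple[int, int]]
                    ) -> CorrelationResult:
    """Pearson correlation with a group mean over its signature genes.

    A zero-variance vector on the signature genes makes the correlation
    undefined; the result is then flagged and reported as 0 rather than
    silently propagating NaN.
    """
    mask = _chromosome_mask(len(group.mean_profile), group.signature_chromosomes,
                            chrom_bounds)
    if mask.sum() < 3:
        raise ValueError("signature selection has fewer than 3 genes")
    x = np.asarray(profile, dtype=float)[mask]
    y = group.mean_profile[mask]
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        return CorrelationResult(0.0, False)
    r = float((xc @ yc) / (nx * ny))
    return CorrelationResult(max(-1.0, min(1.0, r)), True)


def score_cells(cnv: CNVMatrix, groups: Sequence[CNVGroup]
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell statistics against every group.

    Returns a DataFrame (cell_id, cnv_signal genome-wide,
    cnv_signal_signature, best_group, best_correlation,
    correlation_defined) plus the full groups x cells correlation
    matrix.  Without groups, signature statistics fall back to the
    genome-wide signal and correlation 0 / undefined.
    """
    n_cells = len(cnv.cells)
    V = cnv.values
    genome_signal = np.mean(V * V, axis=0)
    if not groups:
        df = pd.DataFrame({
            "cell_id": cnv.cells,
            "cnv_signal": genome_signal,
            "cnv_signal_signature": genome_signal,
            "best_group": "",
            "best_correlation": 0.0,
            "correlation_defined": False,
        })
        return df, np.zeros((0, n_cells))

    n_groups = len(groups)
    corr = np.zeros((n_groups, n_cells))
    defined = np.zeros((n_groups, n_cells), dtype=bool)
    sig_signal = np.zeros((n_groups, n_cells))
    for gi, group in enumerate(groups):
        mask = _chromosome_mask(len(cnv.genes), group.signature_chromosomes,
                                cnv.chrom_bounds)
        if mask.sum() < 3:
            raise ValueError(
                f"group {group.group_id}: signature has fewer than 3 genes")
        A = V[mask, :]
        sig_signal[gi] = np.mean(A * A, axis=0)
        y = group.mean_profile[mask]
        yc = y - y.mean()
        ny = float(np.sqrt(yc @ yc))
        Ac = A - A.mean(axis=0)[None, :]
        na = np.sqrt(np.einsum("gc,gc->c", Ac, Ac))
        ok = (na > 0) & (ny > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (yc @ Ac) / (na * ny)
        corr[gi] = np.clip(np.where(ok, r, 0.0), -1.0, 1.0)
        defined[gi] = ok
    best = np.argmax(corr, axis=0)  # undefined entries carry 0; first-group tiebreak
    cell_ix = np.arange(n_cells)
    any_defined = defined.any(axis=0)
    df = pd.DataFrame({
        "cell_id": cnv.cells,
        "cnv_signal": genome_signal,
        "cnv_signal_signature": sig_signal[best, cell_ix],
        "best_group": np.asarray([g.group_id for g in groups])[best],
        "best_correlation": corr[best, cell_ix],
        "correlation_defined": any_defined,
    })
    df.loc[~any_defined, "best_group"] = ""
    return df, corr


def designate_cells(cnv: CNVMatrix, groups: Sequence[CNVGroup],
                    meta: pd.DataFrame,
                    thresholds: ClassificationThresholds | None = None
                    ) -> DesignationReport:
    """Call every cell malignant or non-malignant.

    Thresholds are the configured quantiles of the reference cells'
    own signature signals and best correlations, so the rule is
    self-calibrating and scale-free.  The AND of the two measures must
    hold strictly for a malignant call.
    """
    thresholds = thresholds or ClassificationThresholds()
    meta = meta.set_index("cell_id")
    missing = [c for c in cnv.cells if c not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} cell(s) missing from metadata, "
                         f"e.g. {missing[:5]}")
    aligned = meta.loc[cnv.cells]
    is_ref = aligned["is_reference"].to_numpy(dtype=bool)
    if not is_ref.any():
        raise ValueError("no reference cells available to calibrate thresholds")

    scores, _ = score_cells(cnv, groups)
    sig = scores["cnv_signal_signature"].to_numpy()
    corr = scores["best_correlation"].to_numpy()
    defined = scores["correlation_defined"].to_numpy(dtype=bool)

    t_sig = float(np.quantile(sig[is_ref], thresholds.signal_quantile))
    t_corr = float(np.quantile(corr[is_ref], thresholds.correlation_quantile))
    malignant = (sig > t_sig) & (corr > t_corr) & defined
    logger.info("designation thresholds: signal > %.4g, correlation > %.4g "
                "(from %d reference cells); %d/%d malignant",
                t_sig, t_corr, int(is_ref.sum()), int(malignant.sum()), len(cnv.cells))

    cells = scores.copy()
    cells.insert(1, "cell_type", aligned["cell_type"].to_numpy())
    cells["designation"] = np.where(malignant, "malignant", "non-malignant")

    cluster_fractions = None
    if "cluster" in aligned.columns:
        tmp = cells.assign(cluster=aligned["cluster"].to_numpy())
        cluster_fractions = (
            tmp.groupby("cluster")["designation"]
            .apply(lambda s: float((s == "malignant").mean()))
            .rename("fraction_malignant")
            .reset_index()
        )
    return DesignationReport(cells=cells, cluster_fractions=cluster_fractions,
                             signal_threshold=t_sig, correlation_threshold=t_corr)
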