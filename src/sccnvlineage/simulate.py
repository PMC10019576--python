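"""Seeded scRNA-seq simulator with planted clonal CNVs.

The generator emulates the inputs of an expression-based CNV lineage
study: a tumor containing a few malignant clones that each carry
whole-chromosome dosage gains/losses, surrounded by diploid stromal
populations (T cells, TAMs, OLGs, ECs, mural cells) that express
lineage marker genes.  The generative assumption is the dosage effect
that underlies all expression-based CNV inference: a gene's expected
count scales proportionally with the copy number of its chromosome.

Counts are drawn as negative binomial,

    count[g, c] ~ NB(mean = mu[g, c], dispersion = alpha)

with

    mu[g, c] = baseline[g] * dosage[clone(c), chrom(g)]
               * libfactor[c] * markerfactor[type(c), g]

and variance mu + alpha * mu^2, followed by an extra zero-inflation
("dropout") step.  Marker genes are expressed at ``marker_fold`` times
baseline in their own cell type and suppressed to a small fraction of
baseline everywhere else, reflecting the lineage specificity of real
marker genes (Cd3e is essentially silent outside T cells).  Library
sizes vary log-normally around a mean of one.

Everything is driven by a single integer seed; the same seed yields a
bit-identical count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotate import DEFAULT_MOUSE_PANEL
from .io import CountMatrix, make_cell_metadata, make_gene_annotation

STROMAL_TYPES = ("T", "TAM", "OLG", "EC", "mural")


@dataclass(frozen=True)
class CNVEvent:
    """A whole-chromosome dosage change.

    dosage is a positive copy-number multiplier: 1.5 is a single-copy
    gain, 0.5 a single-copy loss.  1.0 encodes "no event" and is not a
    valid event.
    """

    chromosome: str
    dosage: float

    def __post_init__(self) -> None:
        if self.dosage <= 0:
            raise ValueError(f"dosage must be positive, got {self.dosage}")
        if self.dosage == 1.0:
            raise ValueError("dosage 1.0 means no event; omit it from event lists")


@dataclass(frozen=True)
class CloneSpec:
    """A malignant clone: its size and its chromosome-scale events."""

    clone_id: str
    n_cells: int
    events: tuple[CNVEvent, ...]

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        chroms = [e.chromosome for e in self.events]
        if len(chroms) != len(set(chroms)):
            raise ValueError(f"clone {self.clone_id}: multiple events on one chromosome")

    @property
    def dosage_by_chromosome(self) -> dict[str, float]:
        return {e.chromosome: e.dosage for e in self.events}


@dataclass
class SimulationConfig:
    """Full description of one simulated dataset.

    chromosomes maps chromosome label -> number of genes, in order.
    dispersion is the negative-binomial dispersion alpha
    (variance = mu + alpha * mu^2).  marker_offtarget_factor scales
    marker-gene expression in every cell type other than the marked
    one, emulating lineage specificity.
    """

    chromosomes: dict[str, int]
    clones: list[CloneSpec] = field(default_factory=list)
    stromal_counts: dict[str, int] = field(default_factory=dict)
    marker_genes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {t: tuple(g) for t, g in DEFAULT_MOUSE_PANEL.items()}
    )
    marker_fold: float = 8.0
    marker_offtarget_factor: float = 1.0 / 64.0
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.3
    libsize_sigma: float = 0.3
    dropout: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.chromosomes.values()):
            raise ValueError("gene counts per chromosome must be non-negative")
        if any(n < 0 for n in self.stromal_counts.values()):
            raise ValueError("stromal cell counts must be non-negative")
        unknown = set(self.stromal_counts) - set(STROMAL_TYPES)
        if unknown:
            raise ValueError(f"unknown stromal type(s): {sorted(unknown)}")
        seen: set[str] = set()
        for t, genes in self.marker_genes.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"marker sets not disjoint: {sorted(overlap)}")
            seen |= set(genes)
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        ids = [c.clone_id for c in self.clones]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate clone_id")
        for clone in self.clones:
            bad = set(clone.dosage_by_chromosome) - set(self.chromosomes)
            if bad:
                raise ValueError(
                    f"clone {clone.clone_id}: events on unknown chromosome(s) {sorted(bad)}"
                )

    @property
    def n_genes(self) -> int:
        return sum(self.chromosomes.values())

    @property
    def n_cells(self) -> int:
        return (sum(c.n_cells for c in self.clones)
                + sum(self.stromal_counts.values()))


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation, for recovery evaluation.

    cells: one row per simulated cell (cell_id, true_type, true_clone;
    true_clone is "" for stromal cells).  clone_events maps clone_id to
    its planted events.  genes records chromosome, position and
    baseline mean per gene.
    """

    cells: pd.DataFrame
    clone_events: dict[str, tuple[CNVEvent, ...]]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.cells["cell_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate cell_id in truth table")

    def write(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def _place_marker_genes(gene_ids: list[str],
                        marker_genes: Mapping[str, Sequence[str]]) -> dict[str, int]:
    """Rename evenly spaced gene slots to the marker gene names.

    Returns marker name -> row index.  Even spacing keeps markers spread
    over the genome instead of stacked on one chromosome.
    """
    flat = [g for genes in marker_genes.values() for g in genes]
    n = len(gene_ids)
    if len(flat) > n:
        raise ValueError("more marker genes than genes in the simulation")
    placed: dict[str, int] = {}
    for j, name in enumerate(flat):
        idx = int((j + 0.5) * n / len(flat))
        gene_ids[idx] = name
        placed[name] = idx
    return placed


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one dataset: (counts, gene annotation, cell metadata, truth).

    Cell metadata carries the true stromal labels (clone cells are
    "malignant-candidate") with ``is_reference`` set for T cells, so the
    pipeline can be run either from these labels or from marker-based
    annotation.  A warning is emitted when a marker gene lands on a
    chromosome that carries a CNV event in any clone (confounding, not
    an error).
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_cells = config.n_genes, config.n_cells
    if n_cells == 0:
        raise ValueError("simulation has no cells")

    # genes: per chromosome, increasing positions
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    chrom_of: list[str] = []
    start_bp: list[int] = []
    for chrom, size in config.chromosomes.items():
        chrom_of.extend([chrom] * size)
        start_bp.extend(((j + 1) * 1000 for j in range(size)))
    marker_rows = _place_marker_genes(gene_ids, config.marker_genes)

    event_chroms = {e.chromosome for c in config.clones for e in c.events}
    for name, row in marker_rows.items():
        if chrom_of[row] in event_chroms:
            warnings.warn(
                f"marker gene {name} lies on CNV-bearing chromosome "
                f"{chrom_of[row]}; marker and dosage effects are confounded"
            )

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_genes)

    # cells: clones first, then stromal types in declared order
    cell_ids: list[str] = []
    cell_type: list[str] = []
    true_clone: list[str] = []
    for clone in config.clones:
        for i in range(clone.n_cells):
            cell_ids.append(f"{clone.clone_id}-{i + 1:04d}")
            cell_type.append("malignant-candidate")
            true_clone.append(clone.clone_id)
    for t in STROMAL_TYPES:
        for i in range(config.stromal_counts.get(t, 0)):
            cell_ids.append(f"{t}-{i + 1:04d}")
            cell_type.append(t)
            true_clone.append("")

    libfactor = rng.lognormal(0.0, config.libsize_sigma, n_cells)
    libfactor /= libfactor.mean()

    # per-gene dosage vector per clone
    chrom_arr = np.asarray(chrom_of)
    dosage_of_clone: dict[str, np.ndarray] = {}
    for clone in config.clones:
        d = np.ones(n_genes)
        for chrom, dosage in clone.dosage_by_chromosome.items():
            d[chrom_arr == chrom] = dosage
        dosage_of_clone[clone.clone_id] = d

    # marker factors: fold-up in the marked type, suppression elsewhere
    all_marker_rows = np.asarray(sorted(marker_rows.values()), dtype=int)
    own_rows_of_type = {
        t: np.asarray([marker_rows[g] for g in genes if g in marker_rows], dtype=int)
        for t, genes in config.marker_genes.items()
    }

    mu = np.empty((n_genes, n_cells))
    for j in range(n_cells):
        m = baseline.copy()
        if true_clone[j]:
            m *= dosage_of_clone[true_clone[j]]
        if all_marker_rows.size:
            m[all_marker_rows] *= config.marker_offtarget_factor
            own = own_rows_of_type.get(cell_type[j])
            if own is not None and own.size:
                m[own] *= config.marker_fold / config.marker_offtarget_factor
        mu[:, j] = m * libfactor[j]

    r = 1.0 / config.dispersion  # NB size parameter
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int32)
    if config.dropout > 0:
        counts[rng.random(counts.shape) < config.dropout] = 0

    cm = CountMatrix(gene_ids, cell_ids, sp.csr_matrix(counts))
    annotation = make_gene_annotation(gene_ids, chrom_of, start_bp)
    meta = make_cell_metadata(cell_ids, cell_type, reference_types=("T",),
                              sample_id=f"sim-seed{config.seed}")
    truth = SyntheticTruth(
        cells=pd.DataFrame({
            "cell_id": cell_ids,
            "true_type": ["malignant" if c else t
                          for t, c in zip(cell_type, true_clone)],
            "true_clone": true_clone,
        }),
        clone_events={c.clone_id: c.events for c in config.clones},
        genes=annotation.assign(baseline_mean=baseline),
    )
    return cm, annotation, meta, truth


def default_paperlike_config(seed: int) -> SimulationConfig:
    """The frozen desk-scale acceptance configuration.

    12,000 genes on 20 chromosomes (600 each); three malignant clones
    (A/B/C: 300/300/200 cells) each carrying 4-8 whole-chromosome
    events drawn without replacement at dosage 0.5 or 1.5; stromal
    populations 300 T / 200 TAM / 150 OLG / 90 EC / 80 mural
    (1,620 cells total).  Event chromosomes and dosages are drawn
    deterministically from the seed.
    """
    crng = np.random.default_rng([int(seed), 101])
    chrom_labels = [str(i) for i in range(1, 21)]
    clones = []
    for clone_id, n_cells in (("A", 300), ("B", 300), ("C", 200)):
        n_events = int(crng.integers(4, 9))
        chroms = crng.choice(len(chrom_labels), size=n_events, replace=False)
        dosages = crng.choice([0.5, 1.5], size=n_events)
        events = tuple(CNVEvent(chrom_labels[int(c)], float(d))
                       for c, d in zip(chroms, dosages))
        clones.append(CloneSpec(clone_id, n_cells, events))
    return SimulationConfig(
        chromosomes={c: 600 for c in chrom_labels},
        clones=clones,
        stromal_counts={"T": 300, "TAM": 200, "OLG": 150, "EC": 90, "mural": 80},
        dispersion=0.3,
        dropout=0.05,
        libsize_sigma=0.3,
        marker_fold=8.0,
        seed=int(seed),
    )


def diploid_only_config(seed: int, n_cells: int = 1000) -> SimulationConfig:
    """A clone-free null dataset for calibration checks.

    Stromal proportions follow the default configuration, scaled to
    ``n_cells`` total (default 1,000); rounding residue is absorbed by
    the T-cell count.
    """
    base = default_paperlike_config(seed)
    weights = {"T": 300, "TAM": 200, "OLG": 150, "EC": 90, "mural": 80}
    total = sum(weights.values())
    counts = {t: int(round(w * n_cells / total)) for t, w in weights.items()}
    counts["T"] += n_cells - sum(counts.values())  # absorb rounding
    return replace(base, clones=[], stromal_counts=counts)
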