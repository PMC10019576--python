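"""End-to-end orchestration: simulate/load -> annotate -> infer -> score.

A run is described by a :class:`RunConfig` holding either input paths
or a simulation configuration (never both).  ``run_pipeline`` executes
every stage, optionally writes all intermediate TSVs plus a manifest
with SHA-256 checksums, and — when ground truth is available — scores
the run with :func:`evaluate_recovery` (designation sensitivity and
specificity, clustering adjusted Rand index against the planted
clones, per-type confusion table).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .annotate import DEFAULT_MOUSE_PANEL, annotate_cells
from .infer import (CNVMatrix, SmoothingParams, center_on_reference, infer_cnv,
                    normalize_log, qc_filter_cells, recenter_per_cell,
                    smooth_moving_average, write_cnv_matrix)
from .io import (CountMatrix, DesignationReport, read_cell_metadata, read_counts,
                 read_gene_annotation, write_cell_metadata, write_counts,
                 write_gene_annotation, write_report)
from .scoring import (ClassificationThresholds, CNVGroup, cluster_cnv_groups,
                      designate_cells)
from .simulate import SimulationConfig, SyntheticTruth, simulate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is inconsistent."""


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``simulation`` and ``input_paths`` must be given.
    ``input_paths`` maps: matrix/genes/barcodes (10x triplet input),
    annotation (gene annotation TSV) and, optionally, metadata (cell
    labels that bypass marker annotation).
    """

    simulation: SimulationConfig | None = None
    input_paths: Mapping[str, str] | None = None
    params: SmoothingParams = field(default_factory=SmoothingParams)
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds)
    k: int = 3
    min_group_size: int = 20
    min_effect: float = 0.05
    signature_overrides: Mapping[str, Sequence[str]] | None = None
    panel: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_MOUSE_PANEL))
    reference_types: tuple[str, ...] = ("T",)
    min_marker_score: float = 0.25
    marker_margin: float = 0.1
    use_marker_annotation: bool = True
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise ConfigError(
                "exactly one of simulation config and input paths must be given")
        if self.k < 1:
            raise ConfigError("k must be at least 1")


@dataclass
class RecoveryMetrics:
    """Designation accuracy against planted ground truth."""

    sensitivity: float
    specificity: float
    ari: float
    confusion: pd.DataFrame
    n_clone_cells: int
    n_stromal_cells: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ari": self.ari,
            "n_clone_cells": self.n_clone_cells,
            "n_stromal_cells": self.n_stromal_cells,
        }


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    report: DesignationReport
    cnv: CNVMatrix
    groups: list[CNVGroup]
    meta: pd.DataFrame
    counts: CountMatrix
    truth: SyntheticTruth | None = None
    metrics: RecoveryMetrics | None = None
    output_files: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, counts: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            logger.info("stage %-12s %6.2fs  %s", name, dt,
                        counts.get(name, ""))
            return False
    return _Timer()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; deterministic for a fixed config and seed."""
    truth: SyntheticTruth | None = None
    if config.simulation is not None:
        counts, annotation, sim_meta, truth = simulate_dataset(config.simulation)
    else:
        paths = dict(config.input_paths)
        counts = read_counts(paths["matrix"], paths["genes"], paths["barcodes"])
        annotation = read_gene_annotation(paths["annotation"])
        sim_meta = (read_cell_metadata(paths["metadata"])
                    if "metadata" in paths else None)
    return _run_from_matrix(counts, annotation, config, sim_meta=sim_meta,
                            truth=truth)


def _run_from_matrix(counts: CountMatrix, annotation: pd.DataFrame,
                     config: RunConfig, sim_meta: pd.DataFrame | None = None,
                     truth: SyntheticTruth | None = None) -> PipelineResult:
    """All stages downstream of input acquisition."""
    stage_counts: dict[str, str] = {
        "input": f"{counts.n_genes} genes x {counts.n_cells} cells"}

    with _stage("qc", stage_counts):
        n0 = counts.n_cells
        counts = qc_filter_cells(counts, max_mito_frac=config.params.max_mito_frac,
                                 max_rbc_frac=config.params.max_rbc_frac)
        stage_counts["qc"] = f"{counts.n_cells}/{n0} cells kept"

    with _stage("normalize", stage_counts):
        norm = normalize_log(counts, config.params)

    with _stage("annotate", stage_counts):
        if config.use_marker_annotation:
            meta = annotate_cells(norm, counts.genes, counts.cells,
                                  panel=config.panel,
                                  min_score=config.min_marker_score,
                                  margin=config.marker_margin,
                                  reference_types=config.reference_types)
        elif sim_meta is not None:
            meta = sim_meta[sim_meta["cell_id"].isin(set(counts.cells))].copy()
        else:
            raise ConfigError("no metadata supplied and marker annotation disabled")
        n_cand = int((meta["cell_type"] == "malignant-candidate").sum())
        stage_counts["annotate"] = (f"{n_cand} candidates, "
                                    f"{int(meta['is_reference'].sum())} reference")

    with _stage("infer-cnv", stage_counts):
        meta_ix = meta.set_index("cell_id")
        is_ref = meta_ix.loc[counts.cells, "is_reference"].to_numpy(dtype=bool)
        centered = center_on_reference(norm, is_ref, counts.cells, config.params)
        cnv = smooth_moving_average(centered, counts.genes, annotation,
                                    config.params, cells=counts.cells)
        if config.params.recenter_cells:
            cnv = recenter_per_cell(cnv)
        stage_counts["infer-cnv"] = f"{len(cnv.genes)} genes smoothed"

    with _stage("cluster", stage_counts):
        candidates = meta.loc[meta["cell_type"] == "malignant-candidate",
                              "cell_id"].tolist()
        k = min(config.k, len(candidates)) if candidates else 0
        if k >= 1 and len(candidates) >= config.min_group_size:
            groups = cluster_cnv_groups(
                cnv, candidates, k, min_group_size=config.min_group_size,
                min_effect=config.min_effect,
                signature_overrides=config.signature_overrides)
        else:
            logger.info("too few candidate cells (%d) to form groups",
                        len(candidates))
            groups = []
        stage_counts["cluster"] = (f"{len(groups)} group(s) from "
                                   f"{len(candidates)} candidates")

    with _stage("designate", stage_counts):
        report = designate_cells(cnv, groups, meta, config.thresholds)
        n_mal = int((report.cells["designation"] == "malignant").sum())
        stage_counts["designate"] = f"{n_mal}/{len(report.cells)} malignant"

    metrics = None
    if truth is not None:
        metrics = evaluate_recovery(report, truth, groups)

    result = PipelineResult(report=report, cnv=cnv, groups=groups, meta=meta,
                            counts=counts, truth=truth, metrics=metrics)
    if config.outdir is not None:
        result.output_files = _write_outputs(config, result, stage_counts)
    return result


def _write_outputs(config: RunConfig, result: PipelineResult,
                   stage_counts: dict[str, str]) -> dict[str, Path]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files.update({f"counts_{k}": p
                  for k, p in write_counts(result.counts, outdir / "counts").items()})
    files["annotation"] = write_gene_annotation(
        result.truth.genes[["gene_id", "chromosome", "start_bp"]]
        if result.truth is not None else
        pd.DataFrame({"gene_id": result.cnv.genes,
                      "chromosome": result.cnv.gene_chromosomes(),
                      "start_bp": np.arange(len(result.cnv.genes))}),
        outdir / "annotation.tsv")
    files["metadata"] = write_cell_metadata(result.meta, outdir / "meta.tsv")
    files["cnv"] = outdir / "cnv.tsv"
    write_cnv_matrix(result.cnv, files["cnv"])
    groups_df = pd.DataFrame(
        [(g.group_id, c, ",".join(g.signature_chromosomes))
         for g in result.groups for c in g.cells],
        columns=["group_id", "cell_id", "signature_chromosomes"])
    files["groups"] = outdir / "groups.tsv"
    groups_df.to_csv(files["groups"], sep="\t", index=False)
    files.update({f"report_{k}": p
                  for k, p in write_report(result.report, outdir / "report").items()})
    if result.truth is not None:
        files["truth"] = outdir / "truth.tsv"
        result.truth.write(files["truth"])
    if result.metrics is not None:
        files["recovery"] = outdir / "recovery.json"
        with open(files["recovery"], "w") as fh:
            json.dump(result.metrics.to_dict(), fh, indent=2, sort_keys=True)
        files["confusion"] = outdir / "confusion.tsv"
        result.metrics.confusion.to_csv(files["confusion"], sep="\t")

    manifest = {
        "package_version": __version__,
        "seed": (config.simulation.seed if config.simulation is not None else None),
        "config": _config_echo(config),
        "stage_counts": stage_counts,
        "files": {k: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                  for k, p in sorted(files.items())},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = manifest_path
    return files


def _config_echo(config: RunConfig) -> dict:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, np.generic)):
            return str(o)
        return str(o)
    return json.loads(json.dumps(dataclasses.asdict(config), default=default))


def evaluate_recovery(report: DesignationReport, truth: SyntheticTruth,
                      groups: Sequence[CNVGroup]) -> RecoveryMetrics:
    """Score designations and clustering against planted ground truth.

    Sensitivity is the fraction of true clone cells designated
    malignant; specificity the fraction of true stromal cells
    designated non-malignant; ARI compares group membership with the
    true clone labels on true clone cells only (cells in no group count
    as their own "none" label).
    """
    truth_ix = truth.cells.set_index("cell_id")
    missing = [c for c in report.cells["cell_id"] if c not in truth_ix.index]
    if missing:
        raise ValueError(f"{len(missing)} report cell(s) absent from truth, "
                         f"e.g. {missing[:5]}")
    cells = report.cells.merge(
        truth.cells[["cell_id", "true_type", "true_clone"]], on="cell_id")

    is_clone = cells["true_clone"].astype(str) != ""
    is_stromal = ~is_clone
    sens = (float((cells.loc[is_clone, "designation"] == "malignant").mean())
            if is_clone.any() else float("nan"))
    spec = (float((cells.loc[is_stromal, "designation"] == "non-malignant").mean())
            if is_stromal.any() else float("nan"))

    group_of = {c: g.group_id for g in groups for c in g.cells}
    clone_cells = cells.loc[is_clone, "cell_id"]
    if len(clone_cells):
        pred = [group_of.get(c, "none") for c in clone_cells]
        true = cells.loc[is_clone, "true_clone"].tolist()
        ari = float(adjusted_rand_score(true, pred))
    else:
        ari = float("nan")

    confusion = pd.crosstab(cells["true_type"], cells["designation"])
    return RecoveryMetrics(sensitivity=sens, specificity=spec, ari=ari,
                           confusion=confusion,
                           n_clone_cells=int(is_clone.sum()),
                           n_stromal_cells=int(is_stromal.sum()))
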