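"""Shared fixtures: small seeded simulations and independent oracles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sccnvlineage import (RunConfig, SimulationConfig, default_paperlike_config,
                          diploid_only_config, run_pipeline, simulate_dataset)
from sccnvlineage.simulate import CloneSpec, CNVEvent


def brute_force_windowed_mean(values: np.ndarray, chromosomes,
                              window: int) -> np.ndarray:
    """Independent oracle: per-gene window mean, never crossing chromosomes.

    ``values`` must already be in chromosome order; ``chromosomes`` gives
    each row's chromosome label.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    chromosomes = np.asarray(chromosomes)
    half = (window - 1) // 2
    out = np.empty_like(values)
    for i in range(values.shape[0]):
        same = np.flatnonzero(chromosomes == chromosomes[i])
        lo = max(i - half, int(same.min()))
        hi = min(i + half, int(same.max()))
        out[i] = values[lo:hi + 1].mean(axis=0)
    return out


def small_two_clone_config(seed: int = 11) -> SimulationConfig:
    """A fast dataset: two clones with disjoint whole-chromosome events."""
    return SimulationConfig(
        chromosomes={str(i): 150 for i in range(1, 7)},
        clones=[CloneSpec("A", 60, (CNVEvent("1", 1.5), CNVEvent("3", 0.5))),
                CloneSpec("B", 60, (CNVEvent("2", 0.5), CNVEvent("5", 1.5)))],
        stromal_counts={"T": 60, "TAM": 40, "OLG": 40, "EC": 30, "mural": 30},
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """(counts, annotation, metadata, truth) of the small two-clone dataset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_two_clone_config())


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline result on the small two-clone dataset (k=2)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(RunConfig(simulation=small_two_clone_config(), k=2))


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline result on the frozen default configuration, seed 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(RunConfig(simulation=default_paperlike_config(1), k=3))


@pytest.fixture(scope="session")
def diploid_run():
    """Full pipeline result on the clone-free null dataset, seed 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(RunConfig(simulation=diploid_only_config(1), k=3))
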