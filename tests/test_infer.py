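"""CNV inference: QC, normalization, centering, smoothing, recentering."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from sccnvlineage import (CountMatrix, InferenceError, SmoothingParams,
                          center_on_reference, infer_cnv, make_cell_metadata,
                          make_gene_annotation, normalize_log, qc_filter_cells,
                          read_cnv_matrix, recenter_per_cell,
                          smooth_moving_average, write_cnv_matrix)
from sccnvlineage.simulate import diploid_only_config, simulate_dataset

from conftest import brute_force_windowed_mean


def _cm(genes, counts, cells=None):
    counts = np.asarray(counts)
    cells = cells or [f"c{j}" for j in range(counts.shape[1])]
    return CountMatrix(genes, cells, sp.csr_matrix(counts))


class TestQC:
    def test_high_hemoglobin_cell_removed_at_5pct(self):
        # cell c0: 6 of 100 counts are hemoglobin -> removed (>=5% rule)
        cm = _cm(["Hba-a1", "gene1"], [[6, 1], [94, 99]])
        out = qc_filter_cells(cm, max_rbc_frac=0.05)
        assert out.cells == ["c1"]

    def test_high_mito_cell_removed(self):
        cm = _cm(["mt-Nd1", "gene1"], [[10, 1], [90, 99]])
        out = qc_filter_cells(cm, max_mito_frac=0.05)
        assert out.cells == ["c1"]

    def test_clean_cell_retained(self):
        cm = _cm(["mt-Nd1", "Hba-a1", "gene1"], [[0], [0], [50]])
        assert qc_filter_cells(cm).cells == ["c0"]

    def test_all_cells_failing_is_an_error(self):
        cm = _cm(["Hba-a1", "gene1"], [[50, 60], [50, 40]])
        with pytest.raises(InferenceError, match="no cells survive"):
            qc_filter_cells(cm)


class TestNormalize:
    def test_zero_count_maps_to_zero(self):
        cm = _cm(["g1", "g2"], [[0, 3], [5, 2]])
        norm = normalize_log(cm, SmoothingParams())
        assert norm[0, 0] == 0.0

    def test_known_value_at_scale_total_library(self):
        # libsize 10,000 and count 9,999 -> log2(1 + 9999) ~ 13.2877
        cm = _cm(["g1", "g2"], [[9999], [1]])
        norm = normalize_log(cm, SmoothingParams())
        assert norm[0, 0] == pytest.approx(np.log2(1 + 9999), abs=1e-12)

    def test_depth_invariance_of_cpm(self):
        cm1 = _cm(["g1", "g2", "g3"], [[4], [6], [10]])
        cm2 = _cm(["g1", "g2", "g3"], [[8], [12], [20]])
        p = SmoothingParams()
        assert np.allclose(normalize_log(cm1, p), normalize_log(cm2, p))

    def test_zero_library_cell_is_an_error(self):
        cm = _cm(["g1"], [[0, 5]])
        with pytest.raises(InferenceError, match="c0"):
            normalize_log(cm, SmoothingParams())


class TestCenterOnReference:
    def test_identical_reference_cells_center_to_zero(self):
        norm = np.tile([[1.0], [2.0]], (1, 30))
        ref = np.ones(30, dtype=bool)
        out = center_on_reference(norm, ref, [f"c{i}" for i in range(30)],
                                  SmoothingParams())
        assert np.allclose(out[:, ref], 0.0)

    def test_cap_bounds_centered_values(self):
        norm = np.zeros((1, 25))
        norm[0, 0] = 5.2 + 0.0  # reference mean stays 0 from the other cells
        ref = np.zeros(25, dtype=bool)
        ref[1:] = True
        out = center_on_reference(norm, ref, [f"c{i}" for i in range(25)],
                                  SmoothingParams(cap=3.0))
        assert out[0, 0] == 3.0

    def test_reference_mean_is_zero_when_nothing_clips(self):
        rng = np.random.default_rng(0)
        norm = rng.normal(0, 0.5, size=(40, 50))
        ref = np.zeros(50, dtype=bool)
        ref[:30] = True
        out = center_on_reference(norm, ref, [f"c{i}" for i in range(50)],
                                  SmoothingParams(cap=100.0))
        assert np.abs(out[:, ref].mean(axis=1)).max() < 1e-9

    def test_too_few_reference_cells_error_names_count(self):
        norm = np.zeros((3, 10))
        ref = np.zeros(10, dtype=bool)
        ref[:4] = True
        with pytest.raises(InferenceError, match="4 reference"):
            center_on_reference(norm, ref, [f"c{i}" for i in range(10)],
                                SmoothingParams())


def _ann(chroms, starts=None):
    n = len(chroms)
    starts = starts if starts is not None else list(range(1, n + 1))
    return make_gene_annotation([f"g{i}" for i in range(n)], chroms, starts)


class TestSmoothing:
    def test_single_spike_window_three(self):
        vals = np.array([[0.0], [0.0], [3.0], [0.0], [0.0]])
        ann = _ann(["1"] * 5)
        cnv = smooth_moving_average(vals, [f"g{i}" for i in range(5)], ann,
                                    SmoothingParams(window_genes=3))
        assert np.allclose(cnv.values.ravel(), [0, 1, 1, 1, 0])

    def test_window_one_is_identity_after_sorting(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 3))
        ann = _ann(["1"] * 4 + ["2"] * 4)
        cnv = smooth_moving_average(vals, [f"g{i}" for i in range(8)], ann,
                                    SmoothingParams(window_genes=1))
        assert np.array_equal(cnv.values, vals)

    def test_window_never_crosses_chromosome_boundary(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 2))
        ann = _ann(["1"] * 3 + ["2"] * 3)
        p = SmoothingParams(window_genes=5)
        before = smooth_moving_average(a, [f"g{i}" for i in range(6)], ann, p)
        b = a.copy()
        b[3:] += 100.0  # edit chromosome 2 only
        after = smooth_moving_average(b, [f"g{i}" for i in range(6)], ann, p)
        assert np.array_equal(before.values[:3], after.values[:3])

    def test_gene_rows_sorted_by_chromosome_then_position(self):
        ann = make_gene_annotation(["a", "b", "c"], ["1", "1", "2"], [100, 50, 10])
        vals = np.array([[1.0], [2.0], [3.0]])
        cnv = smooth_moving_average(vals, ["a", "b", "c"], ann,
                                    SmoothingParams(window_genes=1))
        assert cnv.genes == ["b", "a", "c"]
        assert cnv.chrom_bounds == {"1": (0, 2), "2": (2, 3)}

    @pytest.mark.parametrize("window", [1, 3, 11, 101])
    def test_matches_brute_force_oracle(self, window):
        rng = np.random.default_rng(100 + window)
        n = int(rng.integers(1, 201))
        n_chrom = int(rng.integers(1, 5))
        chroms = np.sort(rng.integers(0, n_chrom, n)).astype(str)
        vals = rng.normal(size=(n, 4))
        ann = _ann(list(chroms))
        cnv = smooth_moving_average(vals, [f"g{i}" for i in range(n)], ann,
                                    SmoothingParams(window_genes=window))
        expected = brute_force_windowed_mean(vals, chroms, window)
        assert np.abs(cnv.values - expected).max() < 1e-12

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_oracle_equivalence_property(self, data):
        n = data.draw(st.integers(1, 60))
        window = data.draw(st.sampled_from([1, 3, 5, 9, 21, 101]))
        n_chrom = data.draw(st.integers(1, 4))
        splits = sorted(data.draw(
            st.lists(st.integers(0, n), max_size=n_chrom - 1, min_size=n_chrom - 1)))
        bounds = [0, *splits, n]
        chroms = np.repeat([str(i) for i in range(n_chrom)], np.diff(bounds))
        vals = np.asarray(data.draw(st.lists(
            st.floats(-100, 100), min_size=n, max_size=n)))[:, None]
        ann = _ann(list(chroms))
        cnv = smooth_moving_average(vals, [f"g{i}" for i in range(n)], ann,
                                    SmoothingParams(window_genes=window))
        expected = brute_force_windowed_mean(vals, chroms, window)
        assert np.abs(cnv.values - expected).max() < 1e-9


class TestRecenter:
    def test_constant_profile_maps_to_zero(self):
        from sccnvlineage.infer import CNVMatrix
        cnv = CNVMatrix(["g0", "g1", "g2"], ["c0"], np.ones((3, 1)),
                        {"1": (0, 3)})
        assert np.allclose(recenter_per_cell(cnv).values, 0.0)

    def test_symmetric_profile_unchanged(self):
        from sccnvlineage.infer import CNVMatrix
        vals = np.array([[-1.0], [0.0], [1.0]])
        cnv = CNVMatrix(["g0", "g1", "g2"], ["c0"], vals, {"1": (0, 3)})
        assert np.array_equal(recenter_per_cell(cnv).values, vals)

    def test_every_cell_median_zero_after_recentering(self):
        from sccnvlineage.infer import CNVMatrix
        rng = np.random.default_rng(4)
        vals = rng.normal(2.0, 1.0, size=(31, 7))
        cnv = CNVMatrix([f"g{i}" for i in range(31)], [f"c{j}" for j in range(7)],
                        vals, {"1": (0, 31)})
        out = recenter_per_cell(cnv)
        assert np.abs(np.median(out.values, axis=0)).max() < 1e-12


class TestInferCNVChain:
    def _uniform_dataset(self):
        rng = np.random.default_rng(9)
        profile = rng.integers(0, 20, size=30)
        counts = np.tile(profile[:, None], (1, 40))
        genes = [f"g{i}" for i in range(30)]
        cm = CountMatrix(genes, [f"c{j}" for j in range(40)],
                         sp.csr_matrix(counts))
        ann = make_gene_annotation(genes, ["1"] * 15 + ["2"] * 15,
                                   list(range(1, 16)) * 2)
        meta = make_cell_metadata(cm.cells, ["T"] * 40, ("T",))
        return cm, ann, meta

    def test_cells_identical_to_reference_give_null_cnv(self):
        cm, ann, meta = self._uniform_dataset()
        cnv = infer_cnv(cm, ann, meta, SmoothingParams(window_genes=5))
        assert np.abs(cnv.values).max() < 1e-9

    def test_gene_row_permutation_leaves_cnv_identical(self):
        cm, ann, meta = self._uniform_dataset()
        rng = np.random.default_rng(10)
        extra = rng.poisson(3.0, size=(30, 40))
        cm = CountMatrix(cm.genes, cm.cells, sp.csr_matrix(cm.to_dense() + extra))
        p = SmoothingParams(window_genes=5)
        base = infer_cnv(cm, ann, meta, p)
        perm = rng.permutation(30)
        cm2 = CountMatrix([cm.genes[i] for i in perm], cm.cells,
                          cm.counts[perm, :])
        other = infer_cnv(cm2, ann, meta, p)
        assert base.genes == other.genes
        assert np.array_equal(base.values, other.values)

    def test_unannotated_genes_dropped(self):
        cm, ann, meta = self._uniform_dataset()
        cnv = infer_cnv(cm, ann.iloc[:-2], meta, SmoothingParams(window_genes=5))
        assert len(cnv.genes) == 28


def test_null_noise_shrinks_with_window_width():
    """On clone-free data the reference |CNV| tail must shrink as the
    smoothing window grows (moving-average noise suppression)."""
    cfg = diploid_only_config(1, n_cells=300)
    cfg = type(cfg)(**{**cfg.__dict__,
                       "chromosomes": {str(i): 300 for i in range(1, 9)}})
    counts, ann, meta, _ = simulate_dataset(cfg)
    ref = meta.set_index("cell_id")
    tails = []
    for window in (11, 51, 101):
        cnv = infer_cnv(counts, ann, meta, SmoothingParams(window_genes=window))
        is_ref = ref.loc[cnv.cells, "is_reference"].to_numpy(bool)
        tails.append(float(np.quantile(np.abs(cnv.values[:, is_ref]), 0.99)))
    assert tails[0] > tails[1] > tails[2]
    assert tails[2] < SmoothingParams().cap


def test_cnv_matrix_tsv_round_trip(tmp_path, small_dataset):
    counts, ann, meta, _ = small_dataset
    cnv = infer_cnv(counts, ann, meta, SmoothingParams(window_genes=11))
    path = tmp_path / "cnv.tsv"
    write_cnv_matrix(cnv, path)
    back = read_cnv_matrix(path)
    assert back.genes == cnv.genes and back.cells == cnv.cells
    assert back.chrom_bounds == cnv.chrom_bounds
    assert np.allclose(back.values, cnv.values, atol=1e-4)
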