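"""Preprocessing: skull-stripping, z-scoring, resampling, expression QC,
log normalization, and gene-graph construction against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mdlca.exceptions import (ConstantVolumeError, DegenerateMaskError,
                              DimensionError, EmptyPanelError)
from mdlca.preprocess import (BrainMask, ExpressionProfile, PreprocessConfig,
                              VolumeImage, apply_brain_mask, build_gene_graph,
                              close_mask, fallback_brain_mask,
                              log_normalize_expression, qc_filter,
                              resize_volume, zscore_normalize)

from conftest import make_profiles


def vol(data, **kw):
    return VolumeImage(data=np.asarray(data, dtype=float), **kw)


class TestApplyBrainMask:
    def test_all_ones_mask_is_identity(self, rng):
        v = vol(rng.normal(size=(5, 5, 5)))
        m = BrainMask(data=np.ones((5, 5, 5), dtype=np.uint8))
        cfg = PreprocessConfig(closing_kernel=1, min_brain_voxels=1)
        np.testing.assert_array_equal(apply_brain_mask(v, m, cfg).data, v.data)

    def test_all_zero_mask_is_degenerate(self):
        v = vol(np.ones((5, 5, 5)))
        m = BrainMask(data=np.zeros((5, 5, 5), dtype=np.uint8))
        with pytest.raises(DegenerateMaskError):
            apply_brain_mask(v, m, PreprocessConfig(closing_kernel=1))

    def test_single_voxel_elementwise_oracle(self):
        v = vol(np.full((4, 4, 4), 2.0))
        mdata = np.zeros((4, 4, 4), dtype=np.uint8)
        mdata[2, 1, 2] = 1
        cfg = PreprocessConfig(closing_kernel=1, min_brain_voxels=1)
        out = apply_brain_mask(v, BrainMask(data=mdata), cfg).data
        for idx in np.ndindex(4, 4, 4):  # exhaustive elementwise check
            expected = 2.0 if idx == (2, 1, 2) else 0.0
            assert out[idx] == expected

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            apply_brain_mask(vol(np.ones((4, 4, 4))),
                             BrainMask(data=np.ones((5, 5, 5), dtype=np.uint8)))

    def test_idempotent_on_closed_mask(self, rng):
        v = vol(rng.normal(size=(8, 8, 8)))
        mdata = np.zeros((8, 8, 8), dtype=np.uint8)
        mdata[2:6, 2:6, 2:6] = 1
        closed = close_mask(BrainMask(data=mdata), 3)
        cfg = PreprocessConfig(closing_kernel=3, min_brain_voxels=1)
        once = apply_brain_mask(v, closed, cfg)
        twice = apply_brain_mask(once, closed, cfg)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_closing_fills_interior_hole(self):
        mdata = np.ones((7, 7, 7), dtype=np.uint8)
        mdata[3, 3, 3] = 0
        closed = close_mask(BrainMask(data=mdata), 3)
        assert closed.data[3, 3, 3] == 1


class TestZscore:
    def test_two_voxel_symmetry(self):
        data = np.zeros((2, 2, 2))
        data[0, 0, 0], data[0, 0, 1] = 1.0, 3.0
        m = np.zeros((2, 2, 2), dtype=np.uint8)
        m[0, 0, :] = 1
        out = zscore_normalize(vol(data), BrainMask(data=m)).data
        assert out[0, 0, 0] == -out[0, 0, 1]
        assert abs(out[0, 0, 0] + out[0, 0, 1]) < 1e-12

    def test_constant_brain_errors(self):
        m = np.ones((3, 3, 3), dtype=np.uint8)
        with pytest.raises(ConstantVolumeError):
            zscore_normalize(vol(np.full((3, 3, 3), 5.0)), BrainMask(data=m))

    def test_hand_computed_mean_sd(self):
        # brain voxels {0..4}: mean 2, sample sd sqrt(2.5)
        data = np.zeros((5, 1, 1))
        data[:, 0, 0] = np.arange(5.0)
        m = np.ones((5, 1, 1), dtype=np.uint8)
        out = zscore_normalize(vol(data), BrainMask(data=m)).data[:, 0, 0]
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1.0) < 1e-12
        assert abs(out[4] - (4 - 2) / np.sqrt(2.5)) < 1e-12

    def test_outside_mask_zeroed_and_idempotent(self, rng):
        data = rng.normal(size=(6, 6, 6)) + 10
        m = np.zeros((6, 6, 6), dtype=np.uint8)
        m[1:5, 1:5, 1:5] = 1
        mask = BrainMask(data=m)
        once = zscore_normalize(vol(data), mask)
        assert np.all(once.data[m == 0] == 0)
        twice = zscore_normalize(once, mask)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)


class TestResize:
    def test_identity_resize_is_bitwise(self, rng):
        v = vol(rng.normal(size=(8, 8, 8)))
        out = resize_volume(v, PreprocessConfig(target_side=8))
        np.testing.assert_array_equal(out.data, v.data)

    @pytest.mark.parametrize("interp", ["trilinear", "nearest"])
    def test_constant_preserved(self, interp):
        v = vol(np.full((10, 6, 9), 7.5))
        out = resize_volume(v, PreprocessConfig(target_side=4,
                                                interpolation=interp))
        assert out.data.shape == (4, 4, 4)
        np.testing.assert_allclose(out.data, 7.5)

    def test_ramp_downsample_midpoints(self):
        # axis-0 ramp 0..7 halved: half-pixel centers hit pair midpoints
        data = np.broadcast_to(np.arange(8.0)[:, None, None], (8, 8, 8)).copy()
        out = resize_volume(vol(data), PreprocessConfig(target_side=4))
        np.testing.assert_allclose(out.data[:, 0, 0], [0.5, 2.5, 4.5, 6.5])

    def test_monotone_ramp_order_preserved(self):
        data = np.broadcast_to(np.arange(12.0)[:, None, None],
                               (12, 12, 12)).copy()
        out = resize_volume(vol(data), PreprocessConfig(target_side=5))
        profile = out.data[:, 2, 2]
        assert np.all(np.diff(profile) > 0)


class TestExpression:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0),
                                            (255.0, 8.0)])
    def test_log2_values(self, x, expected):
        p = ExpressionProfile(values=pd.Series({"g": x}))
        assert log_normalize_expression(p).values["g"] == expected

    def test_negative_raises(self):
        p = ExpressionProfile(values=pd.Series({"g": -1.0}))
        with pytest.raises(ValueError):
            log_normalize_expression(p)

    def test_qc_noop_thresholds(self, rng):
        profiles = make_profiles(rng.uniform(1, 10, size=(4, 5)))
        out = qc_filter(profiles, max_missing_frac=0.5, min_variance=0.0)
        assert out[0].genes == profiles[0].genes

    def test_qc_all_missing_gene_dropped(self, rng):
        mat = rng.uniform(1, 10, size=(3, 4))
        mat[1, :] = np.nan
        out = qc_filter(make_profiles(mat), max_missing_frac=0.2)
        assert [g for g in out[0].genes] == ["G0", "G2"]

    def test_qc_brute_force_oracle(self):
        # 3 genes x 4 patients; thresholds: missing<=0.25, var>=0.5
        mat = np.array([[1.0, 2.0, 3.0, 4.0],       # var 1.25 -> keep
                        [5.0, 5.0, 5.1, np.nan],    # var ~0  -> drop
                        [np.nan, np.nan, 1.0, 2.0]])  # missing 0.5 -> drop
        survivors = []
        for g in range(3):  # exhaustive filter oracle
            row = mat[g]
            miss = np.isnan(row).mean()
            var = np.nanvar(row)
            if miss <= 0.25 and var >= 0.5:
                survivors.append(f"G{g}")
        out = qc_filter(make_profiles(mat), max_missing_frac=0.25,
                        min_variance=0.5)
        assert out[0].genes == survivors == ["G0"]

    def test_qc_median_imputation(self):
        mat = np.array([[1.0, 2.0, np.nan, 4.0]])
        out = qc_filter(make_profiles(mat), max_missing_frac=0.5,
                        min_variance=0.0)
        assert out[2].values["G0"] == 2.0  # median of {1, 2, 4}

    def test_qc_empty_panel(self):
        mat = np.full((2, 3), np.nan)
        with pytest.raises(EmptyPanelError):
            qc_filter(make_profiles(mat))


class TestGeneGraph:
    def test_perfect_correlation_single_edge(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mat = np.vstack([x, 2 * x + 1])
        g = build_gene_graph(make_profiles(mat), corr_threshold=0.9)
        assert g.edges == {(0, 1)}

    def test_anticorrelation_counts_via_absolute_r(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mat = np.vstack([x, -x])
        g = build_gene_graph(make_profiles(mat), corr_threshold=0.9)
        assert g.edges == {(0, 1)}

    def test_five_gene_all_pairs_oracle(self, rng):
        mat = rng.normal(size=(5, 12))
        mat[1] = mat[0] * 0.9 + rng.normal(size=12) * 0.1
        mat[3] = -mat[2] + rng.normal(size=12) * 0.05
        expected = set()
        for i in range(5):  # exhaustive pairwise Pearson oracle
            for j in range(i + 1, 5):
                r = np.corrcoef(mat[i], mat[j])[0, 1]
                if abs(r) >= 0.7:
                    expected.add((i, j))
        g = build_gene_graph(make_profiles(mat), corr_threshold=0.7)
        assert g.edges == expected
        assert len(expected) >= 2

    def test_zero_variance_gene_gets_no_edges(self, rng):
        mat = rng.normal(size=(3, 8))
        mat[1] = 4.2
        g = build_gene_graph(make_profiles(mat), corr_threshold=0.1)
        assert all(1 not in e for e in g.edges)

    def test_patient_order_invariance(self, rng):
        mat = rng.normal(size=(6, 10))
        profiles = make_profiles(mat)
        perm = [3, 1, 4, 0, 2, 5, 7, 9, 8, 6][:10]
        g1 = build_gene_graph(profiles, corr_threshold=0.3)
        g2 = build_gene_graph([profiles[i] for i in perm], corr_threshold=0.3)
        assert g1.edges == g2.edges

    def test_gene_order_invariance_up_to_relabeling(self, rng):
        mat = rng.normal(size=(6, 10))
        perm = np.array([2, 0, 5, 1, 4, 3])
        g1 = build_gene_graph(make_profiles(mat), corr_threshold=0.3)
        genes_p = [f"G{i}" for i in perm]
        g2 = build_gene_graph(make_profiles(mat[perm], genes=genes_p),
                              corr_threshold=0.3)
        inv = {g: k for k, g in enumerate(genes_p)}
        relabeled = {tuple(sorted((inv[f"G{i}"], inv[f"G{j}"])))
                     for i, j in g1.edges}
        assert relabeled == g2.edges

    def test_edge_list_mode_and_unknown_symbol(self, rng):
        profiles = make_profiles(rng.normal(size=(3, 4)))
        g = build_gene_graph(profiles, edge_source="edge_list",
                             edge_list=[("G0", "G1"), ("G1", "G0"),
                                        ("G1", "G2")])
        assert g.edges == {(0, 1), (1, 2)}
        with pytest.raises(KeyError):
            build_gene_graph(profiles, edge_source="edge_list",
                             edge_list=[("G0", "BAD")])


def test_fallback_mask_recovers_bright_blob(rng):
    data = rng.normal(0, 0.05, size=(16, 16, 16))
    data[4:12, 4:12, 4:12] += 5.0
    mask = fallback_brain_mask(VolumeImage(data=data))
    sel = np.zeros((16, 16, 16), dtype=bool)
    sel[4:12, 4:12, 4:12] = True
    assert mask.data[sel].mean() > 0.95
    assert mask.data[~sel].mean() < 0.05
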