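"""Fusion: spatial cross-modal attention (per-cell normalization, residual
identity, enumeration oracle) and modality-attention convex mixing."""

import numpy as np
import pytest

from mdlca._autograd import Tensor, no_grad
from mdlca.exceptions import EmptyGraphError
from mdlca.fusion import (CrossModalGraphAttention, FusedEmbedding,
                          FusionConfig, ModalityAttentionFusion,
                          cross_modal_graph_attention, fuse,
                          modality_attention, project_to_latent,
                          top_genes_by_beta)
from mdlca.genomic_encoder import NodeEmbeddings
from mdlca.mri_encoder import FeatureMap3D


def make_module(channels, gene_dim, cfg=None, seed=0):
    return CrossModalGraphAttention(channels, gene_dim,
                                    cfg or FusionConfig.tiny(seed=seed))


class TestCrossModalAttention:
    def test_single_gene_gets_full_weight(self, rng):
        mod = make_module(4, 3)
        betas = mod.betas(rng.normal(size=(4, 2, 2, 2)),
                          rng.normal(size=(1, 3)))
        np.testing.assert_allclose(betas, 1.0)

    def test_zero_attention_vector_uniform(self, rng):
        mod = make_module(4, 3)
        mod.a_m.data[:] = 0.0
        mod.a_g.data[:] = 0.0
        betas = mod.betas(rng.normal(size=(4, 2, 2, 2)),
                          rng.normal(size=(5, 3)))
        np.testing.assert_allclose(betas, 0.2)

    def test_betas_sum_to_one_per_cell(self, rng):
        mod = make_module(6, 4)
        betas = mod.betas(rng.normal(size=(6, 3, 3, 3)),
                          rng.normal(size=(7, 4)))
        np.testing.assert_allclose(betas.sum(axis=1), 1.0, atol=1e-6)
        assert (betas >= 0).all()

    def test_triple_loop_enumeration_oracle(self, rng):
        """Explicit per-cell, per-gene evaluation of the attention update."""
        C, N, F = 4, 3, 2
        fmap = rng.normal(size=(C, 2, 2, 2))
        genes = rng.normal(size=(N, F))
        mod = make_module(C, F, seed=5)
        out = cross_modal_graph_attention(
            FeatureMap3D(tensor=fmap, patient_id="p"),
            NodeEmbeddings(matrix=genes), module=mod)
        W_m, W_a = mod.W_m.data, mod.W_a.data
        a_m, a_g = mod.a_m.data, mod.a_g.data
        W_msg = mod.W_msg.data
        slope = mod.cfg.leaky_slope
        expected = fmap.copy()
        for x in range(2):
            for y in range(2):
                for z in range(2):
                    f_s = fmap[:, x, y, z]
                    logits = np.empty(N)
                    for i in range(N):
                        pre = (W_m.T @ f_s) @ a_m + (W_a.T @ genes[i]) @ a_g
                        logits[i] = pre if pre > 0 else slope * pre
                    e = np.exp(logits - logits.max())
                    beta = e / e.sum()
                    msg = np.zeros(C)
                    for i in range(N):
                        msg += beta[i] * (W_msg.T @ genes[i])
                    expected[:, x, y, z] += msg
        np.testing.assert_allclose(out.tensor, expected, atol=1e-10)
        assert out.patient_id == "p"

    def test_zero_message_weights_residual_identity(self, rng):
        mod = make_module(5, 3)
        mod.W_msg.data[:] = 0.0
        fmap = rng.normal(size=(5, 2, 2, 2))
        out = cross_modal_graph_attention(FeatureMap3D(tensor=fmap),
                                          NodeEmbeddings(
                                              matrix=rng.normal(size=(4, 3))),
                                          module=mod)
        np.testing.assert_allclose(out.tensor, fmap, atol=1e-12)

    def test_non_residual_returns_pure_message(self, rng):
        cfg = FusionConfig.tiny()
        cfg.residual = False
        mod = make_module(5, 3, cfg=cfg)
        mod.W_msg.data[:] = 0.0
        out = cross_modal_graph_attention(
            FeatureMap3D(tensor=rng.normal(size=(5, 2, 2, 2))),
            NodeEmbeddings(matrix=rng.normal(size=(4, 3))), module=mod)
        np.testing.assert_allclose(out.tensor, 0.0, atol=1e-12)

    def test_gene_permutation_invariance(self, rng):
        mod = make_module(4, 3, seed=2)
        fmap = FeatureMap3D(tensor=rng.normal(size=(4, 2, 2, 2)))
        genes = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        out1 = cross_modal_graph_attention(fmap,
                                           NodeEmbeddings(matrix=genes),
                                           module=mod)
        out2 = cross_modal_graph_attention(fmap,
                                           NodeEmbeddings(matrix=genes[perm]),
                                           module=mod)
        np.testing.assert_allclose(out1.tensor, out2.tensor, atol=1e-10)

    def test_empty_gene_set_raises(self, rng):
        mod = make_module(4, 3)
        with pytest.raises(EmptyGraphError):
            with no_grad():
                mod(Tensor(rng.normal(size=(4, 2, 2, 2))),
                    Tensor(np.zeros((0, 3))))

    def test_output_shape_preserved(self, rng):
        mod = make_module(6, 4)
        fmap = rng.normal(size=(6, 3, 2, 4))
        out = cross_modal_graph_attention(FeatureMap3D(tensor=fmap),
                                          NodeEmbeddings(
                                              matrix=rng.normal(size=(5, 4))),
                                          module=mod)
        assert out.tensor.shape == fmap.shape


class TestModalityAttention:
    def test_projection_identity_and_constant(self, rng):
        cfg = FusionConfig(shared_dim=4, attn_hidden=3, cross_attn_dim=3)
        mod = ModalityAttentionFusion(4, 4, cfg)
        mod.proj_mri.weight.data[:] = np.eye(4)
        mod.proj_mri.bias.data[:] = 0.0
        mod.proj_gene.weight.data[:] = 0.0
        mod.proj_gene.bias.data[:] = 2.5
        v = rng.normal(size=4)
        z_m, z_g = project_to_latent(v, rng.normal(size=4), mod)
        np.testing.assert_allclose(z_m, v)
        np.testing.assert_allclose(z_g, 2.5)

    def test_projection_dense_loop_oracle(self, rng):
        cfg = FusionConfig(shared_dim=3, attn_hidden=2, cross_attn_dim=2)
        mod = ModalityAttentionFusion(5, 4, cfg)
        x = rng.normal(size=5)
        z_m, _ = project_to_latent(x, rng.normal(size=4), mod)
        expected = np.array([  # explicit matrix-vector loop
            sum(x[i] * mod.proj_mri.weight.data[i, j] for i in range(5))
            + mod.proj_mri.bias.data[j] for j in range(3)])
        np.testing.assert_allclose(z_m, expected, atol=1e-12)

    def test_equal_scores_give_half_half(self, rng):
        cfg = FusionConfig(shared_dim=4, attn_hidden=3, cross_attn_dim=3)
        mod = ModalityAttentionFusion(4, 4, cfg)
        z = rng.normal(size=4)
        a_m, a_g = modality_attention(z, z.copy(), mod)
        assert a_m == pytest.approx(0.5) and a_g == pytest.approx(0.5)

    def test_weights_sum_to_one(self, rng):
        cfg = FusionConfig(shared_dim=6, attn_hidden=4, cross_attn_dim=4)
        mod = ModalityAttentionFusion(6, 6, cfg)
        for _ in range(20):
            a_m, a_g = modality_attention(rng.normal(size=6),
                                          rng.normal(size=6), mod)
            assert a_m + a_g == pytest.approx(1.0, abs=1e-6)
            assert a_m >= 0 and a_g >= 0

    def test_two_way_softmax_closed_form(self):
        # scores e and 0 mix as (e^1/(e^1+1), 1/(e^1+1))
        w = np.exp(1.0) / (np.exp(1.0) + 1.0)
        alphas = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        assert alphas[0] == pytest.approx(w)
        fused = fuse(np.ones(3), np.zeros(3), (alphas[0], alphas[1]))
        np.testing.assert_allclose(fused.vector, w)

    def test_saturation_limit(self, rng):
        big = np.array([50.0, 0.0])
        alphas = np.exp(big - big.max())
        alphas /= alphas.sum()
        fused = fuse(np.ones(2), np.full(2, -1.0), tuple(alphas))
        np.testing.assert_allclose(fused.vector, 1.0, atol=1e-12)


class TestFuse:
    def test_weight_one_returns_mri(self, rng):
        z = rng.normal(size=5)
        out = fuse(z, rng.normal(size=5), (1.0, 0.0))
        np.testing.assert_array_equal(out.vector, z)

    def test_identical_vectors_fixed_point(self, rng):
        v = rng.normal(size=5)
        out = fuse(v, v.copy(), (0.3, 0.7))
        np.testing.assert_allclose(out.vector, v, atol=1e-12)

    def test_elementwise_arithmetic(self):
        out = fuse(np.array([4.0, 0.0]), np.array([0.0, 8.0]), (0.25, 0.75))
        np.testing.assert_allclose(out.vector, [1.0, 6.0])
        assert out.modality_weights == (0.25, 0.75)

    def test_convex_combination_bounds(self, rng):
        z_m, z_g = rng.normal(size=6), rng.normal(size=6)
        out = fuse(z_m, z_g, (0.4, 0.6))
        lo, hi = np.minimum(z_m, z_g), np.maximum(z_m, z_g)
        assert np.all(out.vector >= lo - 1e-12)
        assert np.all(out.vector <= hi + 1e-12)

    def test_invalid_weights_raise(self, rng):
        with pytest.raises(ValueError):
            fuse(np.ones(3), np.ones(3), (0.7, 0.7))
        with pytest.raises(ValueError):
            FusedEmbedding(vector=np.ones(3), modality_weights=(-0.1, 1.1))


def test_top_genes_ranking():
    betas = np.array([[0.1, 0.6, 0.3], [0.2, 0.5, 0.3]])
    top = top_genes_by_beta(betas, ["A", "B", "C"], m=2)
    assert [g for g, _ in top] == ["B", "C"]
    assert top[0][1] == pytest.approx(0.55)


def test_fusion_report_jsonl_roundtrip(tmp_path):
    import json
    from mdlca.fusion import write_fusion_report
    records = [{"patient_id": "P0", "alpha_MRI": 0.6, "alpha_Genomic": 0.4,
                "top_genes": [["G1", 0.5]]}]
    path = tmp_path / "report.jsonl"
    write_fusion_report(str(path), records)
    lines = path.read_text().splitlines()
    assert len(lines) == 1
    assert json.loads(lines[0])["alpha_MRI"] == 0.6
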