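"""Graph attention encoder: neighborhood-normalized attention, equivariance,
and agreement with explicit dense-loop evaluation of the update rule."""

import numpy as np
import pytest

from mdlca._autograd import Tensor, no_grad
from mdlca.exceptions import EmptyGraphError, IsolatedNodeError
from mdlca.genomic_encoder import (GATConfig, GATEncoder, GATLayer,
                                   NodeEmbeddings, encode_genome,
                                   export_node_embeddings,
                                   gat_attention_coefficients,
                                   gat_layer_forward)
from mdlca.preprocess import GeneGraph


def path_graph(n, features):
    return GeneGraph(nodes=[f"G{i}" for i in range(n)],
                     edges={(i, i + 1) for i in range(n - 1)},
                     node_features=np.asarray(features, dtype=float))


def brute_force_alphas(graph, X, W, a, slope, self_loops=True):
    """Direct enumeration of the attention softmax per neighborhood."""
    n = graph.n_nodes
    nbrs = {i: set() for i in range(n)}
    for i, j in graph.edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    if self_loops:
        for i in range(n):
            nbrs[i].add(i)
    h = X @ W
    d = W.shape[1]
    out = {}
    for i in range(n):
        logits = {}
        for j in nbrs[i]:
            pre = np.concatenate([h[i], h[j]]) @ a
            logits[j] = pre if pre > 0 else slope * pre
        mx = max(logits.values())
        z = {j: np.exp(v - mx) for j, v in logits.items()}
        total = sum(z.values())
        for j in nbrs[i]:
            out[(i, j)] = z[j] / total
    return out


class TestAttentionCoefficients:
    def test_identical_neighbors_uniform(self):
        g = path_graph(3, np.ones((3, 2)))
        W = np.eye(2)
        a = np.ones(4)
        alphas = gat_attention_coefficients(
            g, NodeEmbeddings(matrix=g.node_features), W, a)
        # middle node has 3 neighbors (2 + self-loop), all identical
        for j in (0, 1, 2):
            assert alphas[(1, j)] == pytest.approx(1 / 3)

    def test_singleton_self_loop(self):
        g = GeneGraph(nodes=["G0"], edges=set(), node_features=[[1.0]])
        alphas = gat_attention_coefficients(
            g, NodeEmbeddings(matrix=g.node_features), np.eye(1), np.ones(2))
        assert alphas[(0, 0)] == pytest.approx(1.0)

    def test_path_graph_matches_enumeration(self, rng):
        X = rng.normal(size=(4, 3))
        g = path_graph(4, X)
        W = rng.normal(size=(3, 2))
        a = rng.normal(size=4)
        got = gat_attention_coefficients(g, NodeEmbeddings(matrix=X), W, a,
                                         leaky_slope=0.2)
        expected = brute_force_alphas(g, X, W, a, slope=0.2)
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-10)

    def test_neighborhood_sums_to_one(self, rng):
        X = rng.normal(size=(6, 3))
        g = GeneGraph(nodes=[f"G{i}" for i in range(6)],
                      edges={(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5),
                             (1, 4)}, node_features=X)
        alphas = gat_attention_coefficients(
            g, NodeEmbeddings(matrix=X), rng.normal(size=(3, 3)),
            rng.normal(size=6))
        for i in range(6):
            total = sum(v for (ii, _), v in alphas.items() if ii == i)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_isolated_node_without_self_loops(self):
        g = GeneGraph(nodes=["A", "B", "C"], edges={(0, 1)},
                      node_features=np.ones((3, 1)))
        with pytest.raises(IsolatedNodeError):
            gat_attention_coefficients(g, NodeEmbeddings(matrix=np.ones((3, 1))),
                                       np.eye(1), np.ones(2),
                                       add_self_loops=False)


class TestLayerForward:
    def test_uniform_attention_gives_neighborhood_mean(self):
        # identical features -> uniform alpha; identity W recovers the mean
        g = path_graph(3, np.ones((3, 2)))
        layer = GATLayer(2, 2, heads=1, activation="identity")
        layer.W.data[0] = np.eye(2)
        layer.a_dst.data[:] = 0.0
        layer.a_src.data[:] = 0.0
        out = gat_layer_forward(g, NodeEmbeddings(matrix=g.node_features),
                                layer)
        np.testing.assert_allclose(out.matrix, 1.0, atol=1e-12)

    def test_five_node_dense_loop_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        g = GeneGraph(nodes=[f"G{i}" for i in range(5)],
                      edges={(0, 1), (1, 2), (2, 3), (3, 4), (0, 4), (1, 3)},
                      node_features=X)
        layer = GATLayer(3, 2, heads=1, activation="identity",
                         rng=np.random.default_rng(4))
        W = layer.W.data[0]
        a = np.concatenate([layer.a_dst.data[0], layer.a_src.data[0]])
        alphas = brute_force_alphas(g, X, W, a, slope=0.2)
        h = X @ W
        expected = np.zeros((5, 2))  # explicit double loop of the update
        for (i, j), alpha in alphas.items():
            expected[i] += alpha * h[j]
        out = gat_layer_forward(g, NodeEmbeddings(matrix=X), layer)
        np.testing.assert_allclose(out.matrix, expected, atol=1e-10)

    def test_node_permutation_equivariance(self, rng):
        X = rng.normal(size=(5, 3))
        edges = {(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)}
        layer = GATLayer(3, 4, heads=2, rng=np.random.default_rng(8))
        perm = np.array([2, 0, 4, 1, 3])
        inv = np.argsort(perm)
        g1 = GeneGraph(nodes=[f"G{i}" for i in range(5)], edges=edges)
        out1 = gat_layer_forward(g1, NodeEmbeddings(matrix=X), layer)
        p_edges = {(int(inv[i]), int(inv[j])) for i, j in edges}
        g2 = GeneGraph(nodes=[f"G{i}" for i in perm], edges=p_edges)
        out2 = gat_layer_forward(g2, NodeEmbeddings(matrix=X[perm]), layer)
        np.testing.assert_allclose(out2.matrix, out1.matrix[perm], atol=1e-10)


class TestEncoder:
    def test_default_embedding_length_256(self, rng):
        g = GeneGraph(nodes=[f"G{i}" for i in range(10)],
                      edges={(i, i + 1) for i in range(9)},
                      node_features=rng.normal(size=(10, 1)))
        pooled, nodes = encode_genome(g, GATConfig())
        assert pooled.shape == (256,)
        assert nodes.matrix.shape == (10, 256)

    def test_single_node_mean_pool_identity(self):
        g = GeneGraph(nodes=["G0"], edges=set(), node_features=[[2.0]])
        pooled, nodes = encode_genome(g, GATConfig.tiny())
        np.testing.assert_allclose(pooled, nodes.matrix[0])

    def test_mean_pool_equals_column_means(self, rng):
        g = GeneGraph(nodes=[f"G{i}" for i in range(6)],
                      edges={(0, 1), (2, 3), (4, 5), (1, 2)},
                      node_features=rng.normal(size=(6, 1)))
        pooled, nodes = encode_genome(g, GATConfig.tiny(), pooling="mean")
        np.testing.assert_allclose(pooled, nodes.matrix.mean(axis=0),
                                   atol=1e-12)

    def test_eval_determinism_bitwise(self, rng):
        g = GeneGraph(nodes=[f"G{i}" for i in range(8)],
                      edges={(i, (i + 1) % 8) for i in range(8)},
                      node_features=rng.normal(size=(8, 1)))
        enc = GATEncoder(GATConfig.tiny(seed=2))
        p1, _ = encode_genome(g, encoder=enc)
        p2, _ = encode_genome(g, encoder=enc)
        np.testing.assert_array_equal(p1, p2)

    def test_pooled_invariant_to_node_permutation(self, rng):
        X = rng.normal(size=(6, 1))
        edges = {(0, 1), (1, 2), (3, 4), (4, 5)}
        enc = GATEncoder(GATConfig.tiny(seed=3))
        g1 = GeneGraph(nodes=[f"G{i}" for i in range(6)], edges=edges,
                       node_features=X)
        perm = np.array([5, 3, 0, 1, 4, 2])
        inv = np.argsort(perm)
        g2 = GeneGraph(nodes=[f"G{i}" for i in perm],
                       edges={(int(inv[i]), int(inv[j])) for i, j in edges},
                       node_features=X[perm])
        p1, _ = encode_genome(g1, encoder=enc)
        p2, _ = encode_genome(g2, encoder=enc)
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_empty_graph_raises(self):
        g = GeneGraph(nodes=[], edges=set())
        with pytest.raises(EmptyGraphError):
            encode_genome(g, GATConfig.tiny())

    def test_per_layer_alpha_normalization_multihead(self, rng):
        g = GeneGraph(nodes=[f"G{i}" for i in range(7)],
                      edges={(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (0, 6)},
                      node_features=rng.normal(size=(7, 1)))
        enc = GATEncoder(GATConfig.tiny(seed=1)).eval()
        ei = g.edge_index(add_self_loops=True)
        x = Tensor(g.node_features)
        for layer in (enc.layer1,):
            for head in range(layer.heads):
                with no_grad():
                    _, alpha = layer.head_forward(x, ei, head,
                                                  return_alpha=True)
                sums = np.zeros(7)
                np.add.at(sums, ei[1], alpha.data)
                np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_export_node_embeddings(tmp_path, rng):
    import pandas as pd
    emb = NodeEmbeddings(matrix=rng.normal(size=(3, 4)),
                         nodes=["A", "B", "C"])
    path = tmp_path / "emb.tsv"
    export_node_embeddings(emb, str(path))
    frame = pd.read_csv(path, sep="\t")
    assert list(frame.columns) == ["gene", "dim_0", "dim_1", "dim_2", "dim_3"]
    assert list(frame["gene"]) == ["A", "B", "C"]
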