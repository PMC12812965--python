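"""Graph attention encoder over the gene-interaction graph.

Two attention layers: the first runs 8 heads whose outputs are concatenated
(ELU nonlinearity), the second a single head producing the final
256-dimensional node embeddings (identity output nonlinearity, as is usual
for a GAT's last layer).  Attention logits use LeakyReLU (slope 0.2) on the
concatenated source/target projections, normalized per neighborhood.
Self-loops are added before attention so every neighborhood is non-empty.
A mean (or max) pool over nodes yields the patient-level embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from ._autograd import Tensor, concat, gather, no_grad, segment_sum
from .exceptions import EmptyGraphError, IsolatedNodeError
from .preprocess import GeneGraph

__all__ = ["GATConfig", "NodeEmbeddings", "GATLayer", "GATEncoder",
           "gat_attention_coefficients", "encode_genome",
           "export_node_embeddings"]


@dataclass
class GATConfig:
    heads_layer1: int = 8
    heads_layer2: int = 1
    hidden_dim: int = 32          # per-head width of layer 1
    out_dim: int = 256
    dropout: float = 0.3
    leaky_slope: float = 0.2
    add_self_loops: bool = True
    in_dim: int = 1               # expression scalar per gene
    seed: int = 0

    def __post_init__(self):
        if self.out_dim % self.heads_layer2:
            raise ValueError("out_dim must be divisible by heads_layer2")

    @classmethod
    def tiny(cls, seed: int = 0) -> "GATConfig":
        return cls(heads_layer1=4, hidden_dim=8, out_dim=32, seed=seed)


@dataclass
class NodeEmbeddings:
    """(N, d) embedding matrix whose row order matches the gene graph."""

    matrix: np.ndarray
    nodes: list[str] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.isfinite(self.matrix).all():
            raise ValueError("node embeddings contain non-finite values")
        if self.nodes is not None and len(self.nodes) != self.matrix.shape[0]:
            raise ValueError("node list length != embedding row count")


def _neighborhood_softmax(logits: Tensor, dst: np.ndarray, n: int) -> Tensor:
    """Softmax of edge logits grouped by destination node."""
    # subtract the per-neighborhood max (constant shift) for stability
    maxes = np.full(n, -np.inf)
    np.maximum.at(maxes, dst, logits.data)
    shifted = logits - Tensor(maxes[dst])
    e = shifted.exp()
    denom = gather(segment_sum(e, dst, n), dst)
    return e / denom


class GATLayer(nn.Module):
    """One multi-head graph attention layer.

    Edges are directed (j -> i aggregates neighbor j into node i); the
    encoder passes both directions of every undirected edge plus self-loops.
    """

    def __init__(self, in_dim: int, out_dim: int, heads: int = 1,
                 concat_heads: bool = True, leaky_slope: float = 0.2,
                 dropout: float = 0.0, activation: str = "elu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.heads, self.concat_heads = heads, concat_heads
        self.leaky_slope = leaky_slope
        self.activation = activation
        self.out_dim = out_dim
        self.W = nn.Parameter(nn.he_normal((heads, in_dim, out_dim), in_dim, rng))
        # attention vector a, split into source/destination halves
        self.a_dst = nn.Parameter(nn.he_normal((heads, out_dim), out_dim, rng))
        self.a_src = nn.Parameter(nn.he_normal((heads, out_dim), out_dim, rng))
        self.attn_dropout = nn.Dropout(dropout, rng=np.random.default_rng(
            rng.integers(2 ** 31)))

    def head_forward(self, x: Tensor, edge_index: np.ndarray, head: int,
                     return_alpha: bool = False):
        src, dst = edge_index
        n = x.shape[0]
        h = x @ self.W[head]                          # (N, out_dim)
        logit_dst = h @ self.a_dst[head]              # a^T [W h_i ...]
        logit_src = h @ self.a_src[head]              # ... || W h_j]
        e = (gather(logit_dst, dst) + gather(logit_src, src)) \
            .leaky_relu(self.leaky_slope)
        alpha = _neighborhood_softmax(e, dst, n)
        alpha = self.attn_dropout(alpha)
        msgs = gather(h, src) * alpha.reshape(-1, 1)
        out = segment_sum(msgs, dst, n)
        if return_alpha:
            return out, alpha
        return out

    def forward(self, x: Tensor, edge_index: np.ndarray) -> Tensor:
        outs = [self.head_forward(x, edge_index, k) for k in range(self.heads)]
        if self.concat_heads:
            out = concat(outs, axis=1) if len(outs) > 1 else outs[0]
        else:
            out = outs[0]
            for o in outs[1:]:
                out = out + o
            out = out * (1.0 / len(outs))
        if self.activation == "elu":
            return out.elu()
        return out


class GATEncoder(nn.Module):
    """Two-layer GAT producing per-node embeddings and a pooled patient
    vector; exposes the pre-pooling node matrix for the cross-modal layer."""

    def __init__(self, cfg: GATConfig | None = None):
        super().__init__()
        cfg = cfg or GATConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.layer1 = GATLayer(cfg.in_dim, cfg.hidden_dim, heads=cfg.heads_layer1,
                               concat_heads=True, leaky_slope=cfg.leaky_slope,
                               dropout=cfg.dropout, activation="elu", rng=rng)
        self.feat_dropout = nn.Dropout(cfg.dropout,
                                       rng=np.random.default_rng(cfg.seed + 1))
        self.layer2 = GATLayer(cfg.hidden_dim * cfg.heads_layer1,
                               cfg.out_dim // cfg.heads_layer2,
                               heads=cfg.heads_layer2, concat_heads=True,
                               leaky_slope=cfg.leaky_slope, dropout=cfg.dropout,
                               activation="identity", rng=rng)

    def _edge_index(self, graph: GeneGraph) -> np.ndarray:
        edge_index = graph.edge_index(add_self_loops=self.cfg.add_self_loops)
        if not self.cfg.add_self_loops:
            present = set(edge_index[1].tolist())
            isolated = [i for i in range(graph.n_nodes) if i not in present]
            if isolated:
                raise IsolatedNodeError(
                    f"nodes {isolated[:5]} have empty neighborhoods and "
                    "self-loops are disabled")
        return edge_index

    def node_forward(self, graph: GeneGraph,
                     features: Tensor | None = None) -> Tensor:
        if graph.n_nodes == 0:
            raise EmptyGraphError("cannot encode an empty gene graph")
        if features is None:
            if graph.node_features is None:
                raise ValueError("graph has no node features attached")
            features = Tensor(graph.node_features)
        edge_index = self._edge_index(graph)
        h = self.layer1(features, edge_index)
        h = self.feat_dropout(h)
        return self.layer2(h, edge_index)

    def forward(self, graph: GeneGraph, features: Tensor | None = None,
                pooling: str = "mean") -> tuple[Tensor, Tensor]:
        """Returns (pooled patient embedding (out_dim,), node matrix (N, d))."""
        nodes = self.node_forward(graph, features)
        if pooling == "mean":
            pooled = nodes.mean(axis=0)
        elif pooling == "max":
            idx = nodes.data.argmax(axis=0)
            pooled = gather(nodes.reshape(-1),
                            idx * nodes.shape[1] + np.arange(nodes.shape[1]))
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        return pooled, nodes


def gat_attention_coefficients(graph: GeneGraph, embeddings: NodeEmbeddings,
                               W: np.ndarray, a: np.ndarray,
                               leaky_slope: float = 0.2,
                               add_self_loops: bool = True
                               ) -> dict[tuple[int, int], float]:
    """Per-edge attention weights for explicit parameters.

    Returns {(i, j): alpha_ij} where alpha_ij is the weight node i places on
    neighbor j; for every node the weights over its neighborhood sum to 1.
    `a` is the full attention vector of length 2 * W.shape[1],
    ordered [destination-half, source-half].
    """
    edge_index = graph.edge_index(add_self_loops=add_self_loops)
    src, dst = edge_index
    if not add_self_loops:
        present = set(dst.tolist())
        isolated = [i for i in range(graph.n_nodes) if i not in present]
        if isolated:
            raise IsolatedNodeError(f"isolated nodes {isolated[:5]}")
    h = embeddings.matrix @ W
    d = W.shape[1]
    a_dst, a_src = np.asarray(a[:d]), np.asarray(a[d:])
    logits = h[dst] @ a_dst + h[src] @ a_src
    logits = np.where(logits > 0, logits, leaky_slope * logits)
    out: dict[tuple[int, int], float] = {}
    for i in np.unique(dst):
        sel = dst == i
        e = np.exp(logits[sel] - logits[sel].max())
        alphas = e / e.sum()
        for j, alpha in zip(src[sel], alphas):
            out[(int(i), int(j))] = float(alpha)
    return out


def gat_layer_forward(graph: GeneGraph, embeddings: NodeEmbeddings,
                      layer: GATLayer, add_self_loops: bool = True
                      ) -> NodeEmbeddings:
    """Run one GAT layer (eval mode) on explicit node embeddings."""
    layer.eval()
    edge_index = graph.edge_index(add_self_loops=add_self_loops)
    with no_grad():
        out = layer(Tensor(embeddings.matrix), edge_index)
    return NodeEmbeddings(matrix=out.data, nodes=embeddings.nodes)


def encode_genome(graph: GeneGraph, cfg: GATConfig | None = None,
                  pooling: str = "mean",
                  encoder: GATEncoder | None = None
                  ) -> tuple[np.ndarray, NodeEmbeddings]:
    """Pooled patient embedding plus the pre-pooling node matrix."""
    if encoder is None:
        encoder = GATEncoder(cfg)
    encoder.eval()
    with no_grad():
        pooled, nodes = encoder(graph, pooling=pooling)
    return pooled.data, NodeEmbeddings(matrix=nodes.data, nodes=list(graph.nodes))


def export_node_embeddings(embeddings: NodeEmbeddings, path: str) -> None:
    """TSV with columns gene, dim_0 ... dim_{d-1}."""
    d = embeddings.matrix.shape[1]
    frame = pd.DataFrame(embeddings.matrix,
                         columns=[f"dim_{i}" for i in range(d)])
    frame.insert(0, "gene", embeddings.nodes or range(len(frame)))
    frame.to_csv(path, sep="\t", index=False)
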