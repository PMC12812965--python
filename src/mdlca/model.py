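"""End-to-end multimodal classifier assembly.

Composition order: (1) volumetric dense encoder -> spatial feature map;
(2) GAT over the gene graph -> node embeddings + pooled patient vector;
(3) cross-modal graph attention injects gene embeddings into the map;
(4) global average pool; (5) modality-attention fusion of the pooled
vectors; (6) dense head -> entmax probabilities.

Ablation variants swap one branch for a deliberately weak stub:
  - "genomic_only": the dense MRI encoder becomes an adaptive mean-pool of
    the raw volume followed by a 1x1x1 linear projection;
  - "mri_only": the GAT becomes a shared per-gene linear map;
  - "concat": both attention fusion stages are replaced by a linear layer on
    the concatenated pooled vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._autograd import Tensor, stack
from .classifier import ClassifierConfig, ClassifierHead
from .fusion import (CrossModalGraphAttention, FusionConfig,
                     ModalityAttentionFusion)
from .genomic_encoder import GATConfig, GATEncoder
from .mri_encoder import DenseNet3D, DenseNetConfig

__all__ = ["ModelConfig", "MDLCAModel", "VARIANTS"]

VARIANTS = ("full", "genomic_only", "mri_only", "concat")


@dataclass
class ModelConfig:
    mri: DenseNetConfig = field(default_factory=DenseNetConfig)
    gat: GATConfig = field(default_factory=GATConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    head: ClassifierConfig = field(default_factory=ClassifierConfig)
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @classmethod
    def tiny(cls, num_classes: int = 3, seed: int = 0,
             variant: str = "full") -> "ModelConfig":
        return cls(mri=DenseNetConfig.tiny(seed=seed),
                   gat=GATConfig.tiny(seed=seed + 1),
                   fusion=FusionConfig.tiny(seed=seed + 2),
                   head=ClassifierConfig.tiny(num_classes=num_classes,
                                              seed=seed + 3),
                   variant=variant)


class _MeanPoolMRIStub(nn.Module):
    """Adaptive mean pool of the raw volume + linear channel lift."""

    def __init__(self, out_channels: int, pooled_side: int,
                 rng: np.random.Generator):
        super().__init__()
        self.pool = nn.AdaptiveAvgPool3d(pooled_side)
        self.lift = nn.Conv3d(1, out_channels, kernel=1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lift(self.pool(x))


class _LinearGeneStub(nn.Module):
    """Shared per-gene linear map standing in for the GAT."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin = nn.Linear(in_dim, out_dim, rng=rng)

    def forward(self, feats: Tensor) -> tuple[Tensor, Tensor]:
        nodes = self.lin(feats)
        return nodes.mean(axis=0), nodes


class MDLCAModel(nn.Module):
    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.mri.seed + 101)
        C, p = cfg.mri.out_channels, cfg.mri.pooled_side
        gat_dim = cfg.gat.out_dim
        if cfg.variant == "genomic_only":
            self.mri_encoder = _MeanPoolMRIStub(C, p, rng)
        else:
            self.mri_encoder = DenseNet3D(cfg.mri)
        if cfg.variant == "mri_only":
            self.gene_encoder = _LinearGeneStub(cfg.gat.in_dim, gat_dim, rng)
        else:
            self.gene_encoder = GATEncoder(cfg.gat)
        if cfg.variant == "concat":
            self.concat_proj = nn.Linear(C + gat_dim, cfg.fusion.shared_dim,
                                         rng=rng)
        else:
            self.cross_attn = CrossModalGraphAttention(C, gat_dim, cfg.fusion)
            self.modality_fusion = ModalityAttentionFusion(C, gat_dim,
                                                           cfg.fusion)
        self.head = ClassifierHead(cfg.fusion.shared_dim, cfg.head)
        self._edge_index: np.ndarray | None = None

    def set_graph(self, graph) -> None:
        """Fix the cohort-level gene-graph topology used by every forward."""
        if self.cfg.variant == "mri_only":
            self._edge_index = None
        else:
            self._edge_index = graph.edge_index(
                add_self_loops=self.cfg.gat.add_self_loops)
        self._graph = graph

    def _encode_genes(self, feats: Tensor) -> tuple[Tensor, Tensor]:
        if self.cfg.variant == "mri_only":
            return self.gene_encoder(feats)
        enc = self.gene_encoder
        h = enc.layer1(feats, self._edge_index)
        h = enc.feat_dropout(h)
        nodes = enc.layer2(h, self._edge_index)
        return nodes.mean(axis=0), nodes

    def forward(self, volumes: Tensor, gene_feats: Tensor,
                return_weights: bool = False):
        """volumes: (B, 1, S, S, S); gene_feats: (B, N, F0) -> logits (B, C)."""
        B = volumes.shape[0]
        fmap = self.mri_encoder(volumes)                     # (B, C, p, p, p)
        pooled_g, node_mats = [], []
        for b in range(B):
            pg, nodes = self._encode_genes(gene_feats[b])
            pooled_g.append(pg)
            node_mats.append(nodes)
        gene_vecs = stack(pooled_g, axis=0)                  # (B, gat_dim)
        if self.cfg.variant == "concat":
            C = fmap.shape[1]
            mri_vecs = fmap.reshape(B, C, -1).mean(axis=2)
            fused = self.concat_proj(_concat_cols(mri_vecs, gene_vecs))
            weights = Tensor(np.full((B, 2), 0.5))
        else:
            attended = stack([self.cross_attn(fmap[b], node_mats[b])
                              for b in range(B)], axis=0)
            C = attended.shape[1]
            mri_vecs = attended.reshape(B, C, -1).mean(axis=2)
            fused, weights = self.modality_fusion(mri_vecs, gene_vecs)
        logits = self.head(fused)
        if return_weights:
            return logits, weights
        return logits


def _concat_cols(a: Tensor, b: Tensor) -> Tensor:
    from ._autograd import concat
    return concat([a, b], axis=1)
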