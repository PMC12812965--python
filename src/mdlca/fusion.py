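"""Two-stage multimodal fusion.

Stage 1 — cross-modal graph attention: every spatial cell of the MRI
feature map attends over the gene-node embeddings; the attended genomic
message (projected into MRI channel space) is added residually to the
cell's feature vector.  Stage 2 — modality attention: the pooled MRI and
genomic vectors are projected into a shared latent space, scored through a
tanh bottleneck, and convexly combined with two-way-softmax weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from ._autograd import Tensor, no_grad, stack
from .exceptions import DimensionError, EmptyGraphError
from .genomic_encoder import NodeEmbeddings
from .mri_encoder import FeatureMap3D

__all__ = ["FusionConfig", "FusedEmbedding", "CrossModalGraphAttention",
           "ModalityAttentionFusion", "cross_modal_graph_attention",
           "project_to_latent", "modality_attention", "fuse",
           "write_fusion_report"]


@dataclass
class FusionConfig:
    shared_dim: int = 256     # d  — latent space of the vector fusion
    attn_hidden: int = 128    # h  — tanh bottleneck of the modality scores
    cross_attn_dim: int = 128 # d' — common space of the spatial attention
    residual: bool = True
    leaky_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.shared_dim, self.attn_hidden, self.cross_attn_dim) < 1:
            raise ValueError("all fusion dimensions must be >= 1")

    @classmethod
    def tiny(cls, seed: int = 0) -> "FusionConfig":
        return cls(shared_dim=32, attn_hidden=16, cross_attn_dim=16, seed=seed)


@dataclass
class FusedEmbedding:
    """Patient-level fused vector with the modality weights that formed it."""

    vector: np.ndarray
    modality_weights: tuple[float, float]  # (alpha_MRI, alpha_Genomic)

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        a_m, a_g = self.modality_weights
        if a_m < 0 or a_g < 0 or abs(a_m + a_g - 1.0) > 1e-6:
            raise ValueError(
                f"modality weights must be a convex pair, got ({a_m}, {a_g})")


class CrossModalGraphAttention(nn.Module):
    """Spatial-cell-over-genes attention with residual genomic injection.

    For cell s and gene i the logit is
    LeakyReLU(a_m . (W_m f_s) + a_g . (W_a g_i)); beta_(s,i) normalizes over
    genes; the message sum_i beta_(s,i) W_msg g_i is added to cell s.
    """

    def __init__(self, channels: int, gene_dim: int,
                 cfg: FusionConfig | None = None):
        super().__init__()
        cfg = cfg or FusionConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dp = cfg.cross_attn_dim
        self.W_m = nn.Parameter(nn.he_normal((channels, dp), channels, rng))
        self.W_a = nn.Parameter(nn.he_normal((gene_dim, dp), gene_dim, rng))
        self.a_m = nn.Parameter(nn.he_normal((dp,), dp, rng))
        self.a_g = nn.Parameter(nn.he_normal((dp,), dp, rng))
        self.W_msg = nn.Parameter(nn.he_normal((gene_dim, channels),
                                               gene_dim, rng))

    def forward(self, fmap: Tensor, genes: Tensor) -> Tensor:
        """fmap: (B, C, D, H, W) or (C, D, H, W); genes: (N, F)."""
        if genes.shape[0] == 0:
            raise EmptyGraphError("cross-modal attention needs >= 1 gene node")
        squeeze = fmap.ndim == 4
        if squeeze:
            fmap = fmap.reshape((1,) + tuple(fmap.shape))
        B, C, D, H, W = fmap.shape
        cells = fmap.reshape(B, C, D * H * W).transpose(0, 2, 1)  # (B, P, C)
        cell_score = (cells @ self.W_m) @ self.a_m                # (B, P)
        gene_score = (genes @ self.W_a) @ self.a_g                # (N,)
        logits = (cell_score.reshape(B, -1, 1) + gene_score.reshape(1, 1, -1)) \
            .leaky_relu(self.cfg.leaky_slope)                     # (B, P, N)
        beta = logits.softmax(axis=-1)
        message = beta @ (genes @ self.W_msg)                     # (B, P, C)
        out = cells + message if self.cfg.residual else message
        out = out.transpose(0, 2, 1).reshape(B, C, D, H, W)
        return out.reshape((C, D, H, W)) if squeeze else out

    def betas(self, fmap: np.ndarray, genes: np.ndarray) -> np.ndarray:
        """Attention coefficients (P, N) for one patient's map (C, D, H, W)."""
        with no_grad():
            cells = Tensor(fmap.reshape(fmap.shape[0], -1).T)
            cs = ((cells @ self.W_m) @ self.a_m).data
            gs = ((Tensor(genes) @ self.W_a) @ self.a_g).data
        logits = cs[:, None] + gs[None, :]
        logits = np.where(logits > 0, logits, self.cfg.leaky_slope * logits)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


class ModalityAttentionFusion(nn.Module):
    """Project both modalities to the shared d-space, score each through
    v^T tanh(W_a z), and mix with the two-way softmax of the scores."""

    def __init__(self, mri_dim: int, gene_dim: int,
                 cfg: FusionConfig | None = None):
        super().__init__()
        cfg = cfg or FusionConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 7)
        d, h = cfg.shared_dim, cfg.attn_hidden
        self.proj_mri = nn.Linear(mri_dim, d, rng=rng)
        self.proj_gene = nn.Linear(gene_dim, d, rng=rng)
        self.W_score = nn.Parameter(nn.he_normal((d, h), d, rng))
        self.v = nn.Parameter(nn.he_normal((h,), h, rng))

    def project(self, mri_vec: Tensor, gene_vec: Tensor) -> tuple[Tensor, Tensor]:
        return self.proj_mri(mri_vec), self.proj_gene(gene_vec)

    def weights(self, z_mri: Tensor, z_gene: Tensor) -> Tensor:
        """Stacked (..., 2) softmax weights (alpha_MRI, alpha_Genomic)."""
        e_mri = (z_mri @ self.W_score).tanh() @ self.v
        e_gene = (z_gene @ self.W_score).tanh() @ self.v
        return stack([e_mri, e_gene], axis=-1).softmax(axis=-1)

    def forward(self, mri_vec: Tensor, gene_vec: Tensor
                ) -> tuple[Tensor, Tensor]:
        """Returns (fused vector(s) (..., d), weights (..., 2))."""
        z_mri, z_gene = self.project(mri_vec, gene_vec)
        alpha = self.weights(z_mri, z_gene)
        a_m = alpha[..., 0:1]
        a_g = alpha[..., 1:2]
        return z_mri * a_m + z_gene * a_g, alpha


# ---------------------------------------------------------------------------
# functional surface (numpy in / numpy out, eval semantics)

def cross_modal_graph_attention(mri_map: FeatureMap3D, gene_nodes: NodeEmbeddings,
                                cfg: FusionConfig | None = None,
                                module: CrossModalGraphAttention | None = None
                                ) -> FeatureMap3D:
    if module is None:
        module = CrossModalGraphAttention(mri_map.tensor.shape[0],
                                          gene_nodes.matrix.shape[1], cfg)
    module.eval()
    with no_grad():
        out = module(Tensor(mri_map.tensor), Tensor(gene_nodes.matrix))
    return FeatureMap3D(tensor=out.data, patient_id=mri_map.patient_id)


def project_to_latent(mri_vec: np.ndarray, gene_vec: np.ndarray,
                      module: ModalityAttentionFusion
                      ) -> tuple[np.ndarray, np.ndarray]:
    with no_grad():
        z_m, z_g = module.project(Tensor(mri_vec), Tensor(gene_vec))
    return z_m.data, z_g.data


def modality_attention(z_mri: np.ndarray, z_gene: np.ndarray,
                       module: ModalityAttentionFusion
                       ) -> tuple[float, float]:
    if z_mri.shape != z_gene.shape:
        raise DimensionError("modality vectors must share the latent shape")
    with no_grad():
        alpha = module.weights(Tensor(z_mri), Tensor(z_gene))
    return float(alpha.data[..., 0]), float(alpha.data[..., 1])


def fuse(z_mri: np.ndarray, z_gene: np.ndarray,
         weights: tuple[float, float]) -> FusedEmbedding:
    a_m, a_g = weights
    if abs(a_m + a_g - 1.0) > 1e-6:
        raise ValueError(f"modality weights must sum to 1, got {a_m + a_g}")
    return FusedEmbedding(vector=a_m * np.asarray(z_mri)
                          + a_g * np.asarray(z_gene),
                          modality_weights=(a_m, a_g))


def write_fusion_report(path: str, records: list[dict]) -> None:
    """JSON-lines interpretability report: one record per patient with
    patient_id, alpha_MRI, alpha_Genomic, and top genes by mean beta."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def top_genes_by_beta(betas: np.ndarray, gene_names: list[str],
                      m: int = 10) -> list[tuple[str, float]]:
    """Rank genes by spatially-averaged attention coefficient."""
    mean_beta = betas.mean(axis=0)
    order = np.argsort(mean_beta)[::-1][:m]
    return [(gene_names[i], float(mean_beta[i])) for i in order]
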