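"""Dense classification head with the sparse entmax-alpha output transform.

entmax-alpha interpolates between softmax (alpha = 1) and sparsemax
(alpha = 2); for alpha > 1 unlikely classes receive exact zeros.  The head
is two dense layers (512 and 128 units, each with batch-norm and ReLU,
dropout 0.3 after the first) followed by a linear logit layer — no
nonlinearity on the logits, which entmax then normalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._autograd import Tensor, entmax_transform, no_grad

__all__ = ["ClassifierConfig", "ClassProbabilities", "ClassifierHead",
           "softmax_probs", "sparsemax_probs", "entmax_probs", "entmax_bisect",
           "entmax",
           "head_forward", "classification_loss", "nll_loss",
           "export_predictions"]


@dataclass
class ClassifierConfig:
    hidden_units: list[int] = field(default_factory=lambda: [512, 128])
    dropout_after_first: float = 0.3
    num_classes: int = 3
    alpha: float = 1.5
    bisect_iters: int = 50
    loss: str = "nll"  # "entmax" (the alpha-entmax loss) is reserved, unbuilt
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_units:
            raise ValueError("hidden_units must be non-empty")
        if not 1.0 <= self.alpha <= 2.0:
            raise ValueError("alpha must lie in [1, 2]")

    @classmethod
    def tiny(cls, num_classes: int = 3, seed: int = 0) -> "ClassifierConfig":
        return cls(hidden_units=[32, 16], num_classes=num_classes, seed=seed)


@dataclass
class ClassProbabilities:
    """Sparse probability vector over tumor classes."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def support(self) -> set[int]:
        return set(np.nonzero(self.probs > 0)[0].tolist())

    @property
    def predicted_class(self) -> int:
        return int(self.probs.argmax())


# ---------------------------------------------------------------------------
# entmax family (numpy, batched over the last axis)

def softmax_probs(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def sparsemax_probs(z: np.ndarray) -> np.ndarray:
    """Sort-based Euclidean projection onto the probability simplex."""
    z = np.asarray(z, dtype=np.float64)
    zs = np.sort(z, axis=-1)[..., ::-1]
    k = np.arange(1, z.shape[-1] + 1)
    cssv = np.cumsum(zs, axis=-1)
    support = 1.0 + k * zs > cssv
    k_star = support.sum(axis=-1, keepdims=True)
    tau = (np.take_along_axis(cssv, k_star - 1, axis=-1) - 1.0) / k_star
    return np.maximum(z - tau, 0.0)


def entmax_bisect(z: np.ndarray, alpha: float, bisect_iters: int = 50
                  ) -> np.ndarray:
    """Bisection solver for alpha-entmax, valid for any alpha in (1, 2].

    Solves for the normalization threshold tau of
    p_i = [(alpha-1) z_i - tau]_+^(1/(alpha-1)); the bracket
    [max(s) - 1, max(s)] always contains tau since the top coordinate alone
    reaches probability 1 at the lower end.
    """
    z = np.asarray(z, dtype=np.float64)
    s = (alpha - 1.0) * z
    expo = 1.0 / (alpha - 1.0)
    # tau in [max(s) - 1, max(s)]: at the upper end sum(p) = 0 (well, -> 0+),
    # at the lower end sum(p) >= 1 since the max coordinate alone reaches 1
    hi = s.max(axis=-1, keepdims=True)
    lo = hi - 1.0
    for _ in range(bisect_iters):
        tau = 0.5 * (lo + hi)
        total = (np.maximum(s - tau, 0.0) ** expo).sum(axis=-1, keepdims=True)
        lo = np.where(total >= 1.0, tau, lo)
        hi = np.where(total >= 1.0, hi, tau)
    tau = 0.5 * (lo + hi)
    p = np.maximum(s - tau, 0.0) ** expo
    return p / p.sum(axis=-1, keepdims=True)


def entmax_probs(z: np.ndarray, alpha: float = 1.5,
                 bisect_iters: int = 50) -> np.ndarray:
    """alpha-entmax along the last axis.

    Exact branches at alpha = 1 (softmax) and alpha = 2 (sparsemax); interior
    alpha is solved by bisection on the normalization threshold.
    """
    z = np.asarray(z, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("entmax requires finite logits")
    if not 1.0 <= alpha <= 2.0:
        raise ValueError("alpha must lie in [1, 2]")
    if alpha == 1.0:
        return softmax_probs(z)
    if alpha == 2.0:
        return sparsemax_probs(z)
    return entmax_bisect(z, alpha, bisect_iters)


def entmax(z: np.ndarray, alpha: float = 1.5,
           bisect_iters: int = 50) -> ClassProbabilities:
    return ClassProbabilities(probs=entmax_probs(z, alpha, bisect_iters))


# ---------------------------------------------------------------------------
# head

class ClassifierHead(nn.Module):
    """fused -> [Linear -> BN -> ReLU (-> Dropout after first)]*L -> logits."""

    def __init__(self, in_dim: int, cfg: ClassifierConfig | None = None):
        super().__init__()
        cfg = cfg or ClassifierConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [in_dim] + list(cfg.hidden_units)
        self.n_hidden = len(cfg.hidden_units)
        for i in range(self.n_hidden):
            setattr(self, f"fc{i}", nn.Linear(dims[i], dims[i + 1],
                                              init="xavier", rng=rng))
            setattr(self, f"bn{i}", nn.BatchNorm1d(dims[i + 1]))
        self.drop = nn.Dropout(cfg.dropout_after_first,
                               rng=np.random.default_rng(cfg.seed + 1))
        self.logit_layer = nn.Linear(dims[-1], cfg.num_classes, init="xavier",
                                     rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(B, d) or (d,) -> logits of matching leading shape."""
        squeeze = x.ndim == 1
        if squeeze:
            x = x.reshape(1, -1)
        for i in range(self.n_hidden):
            x = getattr(self, f"bn{i}")(getattr(self, f"fc{i}")(x)).relu()
            if i == 0:
                x = self.drop(x)
        z = self.logit_layer(x)
        return z.reshape(-1) if squeeze else z

    def predict_proba(self, x: Tensor) -> Tensor:
        return entmax_transform(self.forward(x), alpha=self.cfg.alpha,
                                n_iter=self.cfg.bisect_iters)


def head_forward(fused: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Eval-mode logits for a fused embedding (deterministic)."""
    head.eval()
    with no_grad():
        return head(Tensor(fused)).data


# ---------------------------------------------------------------------------
# loss

_CLAMP_EPS = 1e-8


def nll_loss(probs: Tensor, labels: np.ndarray,
             class_weights: np.ndarray | None = None) -> Tensor:
    """Class-weighted negative log-likelihood on (clamped) probabilities."""
    labels = np.atleast_1d(np.asarray(labels, dtype=np.intp))
    n, c = probs.shape
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    picked = (probs * Tensor(onehot)).sum(axis=1)
    losses = -(picked.clamp_min(_CLAMP_EPS).log())
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        losses = losses * Tensor(w)
    return losses.mean()


def classification_loss(logits: np.ndarray, labels: np.ndarray,
                        class_weights: np.ndarray | None = None,
                        alpha: float = 1.5, kind: str = "nll") -> float:
    """Scalar eval-time loss: NLL of the entmax probabilities."""
    if kind != "nll":
        raise NotImplementedError(
            f"loss kind {kind!r} is a reserved option; only 'nll' is built")
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    probs = entmax_probs(logits, alpha=alpha)
    with no_grad():
        return float(nll_loss(Tensor(probs), labels, class_weights).data)


def export_predictions(path: str, patient_ids: list[str], probs: np.ndarray
                       ) -> None:
    """CSV of patient_id, predicted_class, per-class probabilities, and the
    entmax support size (number of classes with non-zero probability)."""
    import pandas as pd
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    frame = pd.DataFrame(probs, columns=[f"prob_class_{c}"
                                         for c in range(probs.shape[1])])
    frame.insert(0, "patient_id", list(patient_ids))
    frame.insert(1, "predicted_class", probs.argmax(axis=1))
    frame["support_size"] = (probs > 0).sum(axis=1)
    frame.to_csv(path, index=False)
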