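"""End-to-end orchestration: pairing, stratified splitting, augmentation,
training with early stopping, evaluation, and the ablation harness.

Splits are patient-disjoint and stratified by label with largest-remainder
allocation; the validation set is carved from the training portion.  A
leakage guard asserts split disjointness on every run.  Training uses Adam
with optional cosine annealing, class-weighted NLL on entmax probabilities,
and retains the best-validation-loss parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from ._autograd import Tensor, no_grad
from .classifier import entmax_probs, nll_loss
from .evaluation import MetricsReport, compute_confusion, compute_metrics
from .exceptions import StratificationError
from .model import MDLCAModel, ModelConfig, VARIANTS
from .mri_encoder import save_checkpoint
from .preprocess import (BrainMask, ExpressionProfile, PreprocessConfig,
                         VolumeImage, build_gene_graph, load_expression_table,
                         load_mask, load_volume, log_normalize_expression,
                         preprocess_volume, qc_filter)

__all__ = ["TrainConfig", "AugmentConfig", "pair_and_split", "augment_volume",
           "CohortData", "prepare_cohort", "train", "evaluate_model",
           "alpha_sweep", "ablate"]


@dataclass
class AugmentConfig:
    rotation_max_deg: float = 10.0
    contrast_gamma_range: tuple = (0.8, 1.2)
    elastic_sigma: float = 2.0
    elastic_alpha: float = 1.0
    enabled_for_minority_boost: bool = True

    def __post_init__(self):
        lo, hi = self.contrast_gamma_range
        if lo > hi or lo <= 0:
            raise ValueError("contrast_gamma_range must be ordered and positive")


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 8
    lr: float = 1e-4
    weight_decay: float = 1e-5
    scheduler: str = "cosine"      # or "none"
    early_stop_patience: int = 15
    val_fraction: float = 0.15     # of the training split
    test_fraction: float = 0.15
    grad_accum_steps: int = 1
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    use_augmentation: bool = False

    def __post_init__(self):
        if not (0 < self.val_fraction < 1 and 0 < self.test_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")

    @classmethod
    def smoke(cls, seed: int = 0, epochs: int = 30) -> "TrainConfig":
        """Desk-scale preset for CPU smoke training."""
        return cls(epochs=epochs, batch_size=8, lr=3e-3, weight_decay=1e-5,
                   early_stop_patience=epochs, seed=seed)

    @classmethod
    def alternate(cls, seed: int = 0) -> "TrainConfig":
        """The coarser published regime: batch 32 for 50 epochs."""
        return cls(epochs=50, batch_size=32, seed=seed)


# ---------------------------------------------------------------------------
# splitting

def pair_and_split(manifest: pd.DataFrame, test_fraction: float = 0.15,
                   val_fraction: float = 0.15, seed: int = 0
                   ) -> tuple[list[str], list[str], list[str]]:
    """Stratified, patient-disjoint (train, val, test) patient-ID lists.

    Per-class counts use largest-remainder allocation; validation is carved
    from the training portion.
    """
    from .synthetic_data import largest_remainder
    if manifest["patient_id"].duplicated().any():
        raise ValueError("manifest has duplicate patient ids")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for lab, group in manifest.groupby("label"):
        ids = sorted(group["patient_id"].tolist())
        if len(ids) < 3:
            raise StratificationError(
                f"class {lab} has {len(ids)} patients (< 3)")
        by_class[int(lab)] = ids
    n = len(manifest)
    labels = sorted(by_class)
    sizes = np.array([len(by_class[c]) for c in labels], dtype=float)
    n_test = int(round(n * test_fraction))
    test_counts = largest_remainder(n_test, sizes / sizes.sum())
    train_ids, val_ids, test_ids = [], [], []
    leftover_sizes = []
    leftovers = []
    for c, t_count in zip(labels, test_counts):
        ids = list(by_class[c])
        rng.shuffle(ids)
        test_ids += ids[:t_count]
        leftovers.append(ids[t_count:])
        leftover_sizes.append(len(ids) - t_count)
    n_train_pool = sum(leftover_sizes)
    n_val = int(round(n_train_pool * val_fraction))
    val_counts = largest_remainder(
        n_val, np.array(leftover_sizes, dtype=float) / n_train_pool)
    for ids, v_count in zip(leftovers, val_counts):
        val_ids += ids[:v_count]
        train_ids += ids[v_count:]
    _assert_disjoint(train_ids, val_ids, test_ids)
    return sorted(train_ids), sorted(val_ids), sorted(test_ids)


def _assert_disjoint(*splits: list[str]) -> None:
    """Leakage guard: no patient id in more than one split."""
    seen: set[str] = set()
    for split in splits:
        overlap = seen & set(split)
        if overlap:
            raise AssertionError(f"patient leakage across splits: {overlap}")
        seen |= set(split)


# ---------------------------------------------------------------------------
# augmentation

def augment_volume(volume: VolumeImage, cfg: AugmentConfig,
                   rng: np.random.Generator) -> VolumeImage:
    """Random rotation, gamma contrast, and elastic deformation (in that
    order); shape is preserved and zero magnitudes give the identity."""
    data = volume.data
    if cfg.rotation_max_deg > 0:
        angle = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg)
        axes = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
        data = ndimage.rotate(data, angle, axes=axes, reshape=False, order=1,
                              mode="nearest")
    lo, hi = cfg.contrast_gamma_range
    if (lo, hi) != (1.0, 1.0):
        gamma = rng.uniform(lo, hi)
        dmin, dptp = data.min(), np.ptp(data)
        if dptp > 0:
            data = ((data - dmin) / dptp) ** gamma * dptp + dmin
    if cfg.elastic_alpha > 0:
        disp = [ndimage.gaussian_filter(
            rng.uniform(-1, 1, size=data.shape), cfg.elastic_sigma)
            * cfg.elastic_alpha for _ in range(3)]
        grid = np.meshgrid(*[np.arange(s) for s in data.shape], indexing="ij")
        coords = np.array([g + d for g, d in zip(grid, disp)])
        data = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
    return VolumeImage(data=data, spacing=volume.spacing, id=volume.id)


# ---------------------------------------------------------------------------
# cohort assembly

@dataclass
class CohortData:
    """Preprocessed tensors ready for the model, keyed by patient order."""

    patient_ids: list[str]
    volumes: np.ndarray        # (n, 1, S, S, S)
    gene_feats: np.ndarray     # (n, N, 1)
    labels: np.ndarray         # (n,)
    graph: object              # GeneGraph (cohort-level topology)
    gene_names: list[str]


def prepare_cohort(volumes: list[VolumeImage], masks: list[BrainMask | None],
                   profiles: list[ExpressionProfile], labels: list[int],
                   patient_ids: list[str],
                   pre_cfg: PreprocessConfig | None = None,
                   corr_threshold: float = 0.7,
                   graph_ids: list[str] | None = None) -> CohortData:
    """Preprocess both modalities and build the gene graph.

    `graph_ids` restricts correlation-graph estimation to those patients
    (pass the training split to avoid test-set leakage into the topology).
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    vols = [preprocess_volume(v, m, pre_cfg) for v, m in zip(volumes, masks)]
    filtered = qc_filter(profiles)
    normed = [log_normalize_expression(p) for p in filtered]
    graph_profiles = normed if graph_ids is None else \
        [p for p in normed if p.patient_id in set(graph_ids)]
    graph = build_gene_graph(graph_profiles, edge_source="correlation",
                             corr_threshold=corr_threshold)
    feats = np.stack([p.values.reindex(graph.nodes).to_numpy()[:, None]
                      for p in normed])
    return CohortData(
        patient_ids=list(patient_ids),
        volumes=np.stack([v.data[None] for v in vols]),
        gene_feats=feats,
        labels=np.asarray(labels, dtype=np.intp),
        graph=graph,
        gene_names=list(graph.nodes))


def load_cohort_dir(data_dir: str) -> dict:
    """Read a simulated/real cohort directory back into memory."""
    root = Path(data_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    profiles = load_expression_table(str(root / "expression.tsv"))
    prof_by_id = {p.patient_id: p for p in profiles}
    out = {"volumes": [], "masks": [], "profiles": [], "labels": [],
           "patient_ids": [], "manifest": manifest}
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        out["volumes"].append(load_volume(row["image_path"], patient_id=pid))
        mask_path = row.get("mask_path")
        out["masks"].append(load_mask(mask_path)
                            if isinstance(mask_path, str) and mask_path
                            else None)
        out["profiles"].append(prof_by_id[pid])
        out["labels"].append(int(row["label"]))
        out["patient_ids"].append(pid)
    return out


# ---------------------------------------------------------------------------
# training

def _class_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = labels.size / (n_classes * counts)
    return w


def _index_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def _forward_loss(model: MDLCAModel, vols: np.ndarray, feats: np.ndarray,
                  labels: np.ndarray, weights: np.ndarray
                  ) -> tuple[Tensor, np.ndarray]:
    from ._autograd import entmax_transform
    logits = model(Tensor(vols), Tensor(feats))
    probs = entmax_transform(logits, alpha=model.cfg.head.alpha,
                             n_iter=model.cfg.head.bisect_iters)
    loss = nll_loss(probs, labels, class_weights=weights)
    return loss, probs.data


def _minority_boost(vols: np.ndarray, feats: np.ndarray, labels: np.ndarray,
                    aug_cfg: AugmentConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Append augmented copies of minority-class samples up to class balance."""
    counts = np.bincount(labels)
    target = counts.max()
    extra_v, extra_f, extra_l = [], [], []
    for c, count in enumerate(counts):
        pool = np.where(labels == c)[0]
        for k in range(target - count):
            src = pool[k % len(pool)]
            vol = VolumeImage(data=vols[src, 0], id=f"aug{c}_{k}")
            aug = augment_volume(vol, aug_cfg, rng)
            extra_v.append(aug.data[None])
            extra_f.append(feats[src])
            extra_l.append(c)
    if not extra_v:
        return vols, feats, labels
    return (np.concatenate([vols, np.stack(extra_v)]),
            np.concatenate([feats, np.stack(extra_f)]),
            np.concatenate([labels, np.array(extra_l, dtype=labels.dtype)]))


@dataclass
class TrainResult:
    model: MDLCAModel
    history: list[dict]
    best_epoch: int
    best_val_loss: float
    splits: tuple[list[str], list[str], list[str]]
    test_metrics: MetricsReport | None = None


def train(train_cfg: TrainConfig, model_cfg: ModelConfig, cohort: CohortData,
          log_path: str | None = None,
          checkpoint_path: str | None = None,
          val_loss_stream: list[float] | None = None) -> TrainResult:
    """Train one model on a prepared cohort.

    `val_loss_stream` substitutes scripted validation losses (testing the
    early-stopping logic without real training signal).
    """
    manifest = pd.DataFrame({"patient_id": cohort.patient_ids,
                             "label": cohort.labels})
    tr_ids, va_ids, te_ids = pair_and_split(
        manifest, train_cfg.test_fraction, train_cfg.val_fraction,
        train_cfg.seed)
    pos = {pid: i for i, pid in enumerate(cohort.patient_ids)}
    tr_idx = np.array([pos[p] for p in tr_ids], dtype=np.intp)
    va_idx = np.array([pos[p] for p in va_ids], dtype=np.intp)
    te_idx = np.array([pos[p] for p in te_ids], dtype=np.intp)

    model = MDLCAModel(model_cfg)
    model.set_graph(cohort.graph)
    n_classes = model_cfg.head.num_classes
    weights = _class_weights(cohort.labels[tr_idx], n_classes)
    opt = nn.Adam(model.parameters(), lr=train_cfg.lr,
                  weight_decay=train_cfg.weight_decay)
    sched = nn.CosineAnnealingLR(opt, train_cfg.epochs) \
        if train_cfg.scheduler == "cosine" else None
    rng = np.random.default_rng(train_cfg.seed + 17)

    tr_vols = cohort.volumes[tr_idx]
    tr_feats = cohort.gene_feats[tr_idx]
    tr_labels = cohort.labels[tr_idx]
    if train_cfg.use_augmentation and train_cfg.augment.enabled_for_minority_boost:
        tr_vols, tr_feats, tr_labels = _minority_boost(
            tr_vols, tr_feats, tr_labels, train_cfg.augment,
            np.random.default_rng(train_cfg.seed + 29))

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_improve = 0
    history: list[dict] = []
    for epoch in range(1, train_cfg.epochs + 1):
        model.train()
        ep_losses, ep_correct, ep_n = [], 0, 0
        for k, batch in enumerate(_index_batches(len(tr_labels),
                                                 train_cfg.batch_size, rng)):
            loss, probs = _forward_loss(model, tr_vols[batch],
                                        tr_feats[batch], tr_labels[batch],
                                        weights)
            model.zero_grad()
            loss.backward()
            if np.isnan(loss.data):
                raise RuntimeError(
                    f"NaN training loss at epoch {epoch}, batch {k}")
            if (k + 1) % train_cfg.grad_accum_steps == 0:
                opt.step()
                opt.zero_grad()
            ep_losses.append(float(loss.data))
            ep_correct += int((probs.argmax(1) == tr_labels[batch]).sum())
            ep_n += len(batch)
        model.eval()
        if val_loss_stream is not None:
            val_loss = val_loss_stream[min(epoch - 1,
                                           len(val_loss_stream) - 1)]
            val_acc = np.nan
        else:
            with no_grad():
                vloss, vprobs = _forward_loss(
                    model, cohort.volumes[va_idx], cohort.gene_feats[va_idx],
                    cohort.labels[va_idx], weights)
            val_loss = float(vloss.data)
            val_acc = float((vprobs.argmax(1)
                             == cohort.labels[va_idx]).mean())
        record = {"epoch": epoch, "train_loss": float(np.mean(ep_losses)),
                  "train_acc": ep_correct / max(ep_n, 1),
                  "val_loss": val_loss, "val_acc": val_acc,
                  "lr": opt.lr}
        history.append(record)
        if log_path:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(record) + "\n")
        if val_loss < best_val - 1e-12:
            best_val, best_epoch = val_loss, epoch
            best_state = model.state_dict()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= train_cfg.early_stop_patience:
                break
        if sched:
            sched.step()
    model.load_state_dict(best_state)
    model.eval()
    if checkpoint_path:
        save_checkpoint(model, checkpoint_path,
                        meta={"best_epoch": best_epoch,
                              "best_val_loss": best_val})
    result = TrainResult(model=model, history=history, best_epoch=best_epoch,
                         best_val_loss=best_val,
                         splits=(tr_ids, va_ids, te_ids))
    if len(te_idx):
        result.test_metrics = evaluate_model(model, cohort, te_idx)
    return result


def evaluate_model(model: MDLCAModel, cohort: CohortData,
                   idx: np.ndarray | None = None) -> MetricsReport:
    if idx is None:
        idx = np.arange(len(cohort.patient_ids))
    model.eval()
    with no_grad():
        logits = model(Tensor(cohort.volumes[idx]),
                       Tensor(cohort.gene_feats[idx]))
    probs = entmax_probs(logits.data, alpha=model.cfg.head.alpha)
    preds = probs.argmax(axis=1)
    n_classes = model.cfg.head.num_classes
    cm = compute_confusion(cohort.labels[idx], preds, n_classes)
    return compute_metrics(cm, probs=probs, true_labels=cohort.labels[idx])


def alpha_sweep(model: MDLCAModel, cohort: CohortData, idx: np.ndarray,
                alphas=(1.2, 1.3, 1.5, 1.8)) -> pd.DataFrame:
    """Evaluate one trained model under different entmax sparsity levels.

    Returns accuracy and mean support size per alpha — the harness for
    choosing alpha on a validation split.
    """
    model.eval()
    with no_grad():
        logits = model(Tensor(cohort.volumes[idx]),
                       Tensor(cohort.gene_feats[idx])).data
    rows = []
    for alpha in alphas:
        probs = entmax_probs(logits, alpha=alpha)
        rows.append({"alpha": alpha,
                     "accuracy": float((probs.argmax(1)
                                        == cohort.labels[idx]).mean()),
                     "mean_support": float((probs > 0).sum(axis=1).mean())})
    return pd.DataFrame(rows).set_index("alpha")


def ablate(train_cfg: TrainConfig, model_cfg: ModelConfig,
           cohort: CohortData) -> pd.DataFrame:
    """Train the four variants on identical splits/seeds; returns a
    4-row table of held-out accuracy/precision/recall/F1."""
    from dataclasses import replace
    rows = []
    for variant in VARIANTS:
        cfg = replace(model_cfg, variant=variant)
        result = train(train_cfg, cfg, cohort)
        m = result.test_metrics
        rows.append({"variant": variant, "accuracy": m.accuracy,
                     "precision": m.precision, "recall": m.recall,
                     "f1": m.f1})
    return pd.DataFrame(rows).set_index("variant")
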