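"""Classification metrics: confusion matrices, the standard rate metrics
(accuracy, precision, recall, F1, specificity), natural-log log-loss, and
rank-statistic ROC/AUC, with macro one-vs-rest averaging for multiclass.

Probability clamping (eps = 1e-8) guards the log-loss against the exact
zeros the entmax output produces for improbable classes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ConfusionMatrix", "MetricsReport", "compute_confusion",
           "compute_metrics", "binary_auc", "roc_points", "evaluate"]

_CLAMP_EPS = 1e-8


@dataclass
class ConfusionMatrix:
    """C x C counts with rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or \
                self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, c: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating class c as positive."""
        tp = int(self.counts[c, c])
        fn = int(self.counts[c].sum() - tp)
        fp = int(self.counts[:, c].sum() - tp)
        tn = self.n_samples - tp - fn - fp
        return tp, tn, fp, fn

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.counts).to_csv(path, index=True)


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    log_loss: float | None = None
    auc: float | None = None
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("accuracy", "precision", "recall", "f1", "specificity",
                "log_loss", "auc")}
        out["per_class"] = {str(k): v for k, v in self.per_class.items()}
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_confusion(true_labels, predicted_labels, n_classes: int
                      ) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=np.intp)
    p = np.asarray(predicted_labels, dtype=np.intp)
    if t.shape != p.shape:
        raise ValueError("label arrays differ in length")
    if t.size and (min(t.min(), p.min()) < 0
                   or max(t.max(), p.max()) >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts=counts)


def _rates(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    out: dict[str, float] = {}
    out["precision"] = tp / (tp + fp) if tp + fp else np.nan
    out["recall"] = tp / (tp + fn) if tp + fn else np.nan
    out["specificity"] = tn / (tn + fp) if tn + fp else np.nan
    pr, rc = out["precision"], out["recall"]
    if np.isnan(pr) or np.isnan(rc) or pr + rc == 0:
        out["f1"] = np.nan if np.isnan(pr) or np.isnan(rc) else 0.0
    else:
        out["f1"] = 2 * pr * rc / (pr + rc)
    return out


def binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic (ties share ranks)."""
    y = np.asarray(y_true, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def log_loss(true_labels: np.ndarray, probs: np.ndarray) -> float:
    """Natural-log multiclass cross-entropy with probability clamping."""
    t = np.asarray(true_labels, dtype=np.intp)
    p = np.clip(np.asarray(probs, dtype=np.float64), _CLAMP_EPS, 1.0)
    return float(-np.mean(np.log(p[np.arange(t.size), t])))


def compute_metrics(cm: ConfusionMatrix, probs: np.ndarray | None = None,
                    true_labels: np.ndarray | None = None) -> MetricsReport:
    """Metrics from a confusion matrix, optionally with predicted
    probabilities (rows summing to 1) for log-loss and AUC.

    Binary (C = 2) uses class 1 as positive; multiclass macro-averages the
    one-vs-rest rates.  A class absent from the truth has undefined recall
    and is excluded from macro means with a warning.
    """
    c = cm.n_classes
    accuracy = np.trace(cm.counts) / cm.n_samples if cm.n_samples else np.nan
    per_class: dict[int, dict[str, float]] = {}
    for k in range(c):
        per_class[k] = _rates(*cm.one_vs_rest(k))
    if c == 2:
        summary = dict(per_class[1])
    else:
        absent = [k for k in range(c) if cm.counts[k].sum() == 0]
        if absent:
            warnings.warn(f"classes {absent} absent from truth; "
                          "excluded from macro averages", stacklevel=2)
        summary = {}
        for key in ("precision", "recall", "specificity", "f1"):
            vals = [per_class[k][key] for k in range(c)
                    if not np.isnan(per_class[k][key])]
            summary[key] = float(np.mean(vals)) if vals else np.nan
    report = MetricsReport(accuracy=float(accuracy), per_class=per_class,
                           **{k: float(summary[k]) for k in
                              ("precision", "recall", "f1", "specificity")})
    if probs is not None and true_labels is not None:
        probs = np.asarray(probs, dtype=np.float64)
        t = np.asarray(true_labels, dtype=np.intp)
        report.log_loss = log_loss(t, probs)
        aucs = []
        for k in range(c):
            if 0 < (t == k).sum() < t.size:
                auc_k = binary_auc(t == k, probs[:, k])
                per_class[k]["auc"] = auc_k
                aucs.append(auc_k)
        report.auc = float(np.mean(aucs)) if aucs else None
    return report


def roc_points(y_true: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC curve as (fpr, tpr, threshold) rows, thresholds descending."""
    y = np.asarray(y_true, dtype=bool)
    order = np.argsort(scores)[::-1]
    s, yy = np.asarray(scores)[order], y[order]
    tps = np.cumsum(yy)
    fps = np.cumsum(~yy)
    keep = np.r_[np.diff(s) != 0, True]
    tpr = tps[keep] / max(yy.sum(), 1)
    fpr = fps[keep] / max((~yy).sum(), 1)
    return pd.DataFrame({"fpr": np.r_[0.0, fpr], "tpr": np.r_[0.0, tpr],
                         "threshold": np.r_[np.inf, s[keep]]})


def evaluate(true_labels, predicted_labels, probs=None,
             n_classes: int | None = None) -> MetricsReport:
    """Convenience wrapper: confusion + metrics in one call."""
    t = np.asarray(true_labels, dtype=np.intp)
    if n_classes is None:
        n_classes = int(max(t.max(), np.asarray(predicted_labels).max())) + 1
    cm = compute_confusion(t, predicted_labels, n_classes)
    return compute_metrics(cm, probs=probs, true_labels=t)
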