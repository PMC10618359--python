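"""Training regimen and evaluation metrics for the grading network.

Training follows the published regimen: Adam, initial learning rate 2e-4,
batch size 32, 50 epochs, shuffled mini-batches, focal loss; after every epoch
the model is scored on the held-out split and the best-accuracy weights are
retained.  Note the held-out split doubles as both validation (model
selection) and test set, which makes the reported accuracy mildly optimistic
— the protocol is mirrored as published.

Evaluation produces per-class one-vs-rest confusion counts and the derived
accuracy, precision, specificity, recall and F1, plus support-weighted
averages avg = Σ k_i·N_i / Σ N_i (macro averaging is available behind a
flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn
from .dataset import normalize_for_model, resize_bicubic
from .model import DVGG
from .segmentation import segment_mushroom
from .thresholding import OOAConfig

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "TrainResult",
    "focal_loss",
    "focal_loss_grad",
    "train",
    "recalibrate_batchnorm",
    "evaluate",
    "metrics_from_predictions",
    "predict",
    "load_images",
]

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Published defaults: LR 2e-4, batch 32, 50 epochs, Adam, focal loss γ=2."""

    learning_rate: float = 2e-4
    batch_size: int = 32
    epochs: int = 50
    focal_gamma: float = 2.0
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

def focal_loss(probs: np.ndarray, labels: np.ndarray, gamma: float = 2.0) -> float:
    """Mean of −(1 − p_t)^γ · log p_t over the batch.

    ``probs`` rows are class distributions (each sums to 1); γ=0 reduces to
    cross-entropy.  p_t = 0 is clamped by a small epsilon rather than raising.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p_t = np.clip(probs[np.arange(len(labels)), labels], _EPS, 1.0)
    return float(np.mean(-((1.0 - p_t) ** gamma) * np.log(p_t)))


def focal_loss_grad(logits: np.ndarray, labels: np.ndarray, gamma: float = 2.0) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the logits (softmax included).

    With ℓ = −(1−p_t)^γ log p_t and p = softmax(z),
    dℓ/dz_j = [γ(1−p_t)^{γ−1} log p_t − (1−p_t)^γ / p_t] · p_t (δ_tj − p_j),
    averaged over the batch.  γ=0 gives the familiar (p − onehot)/n.
    """
    labels = np.asarray(labels, dtype=np.intp)
    p = nn.softmax(np.asarray(logits, dtype=np.float64), axis=1)
    n = len(labels)
    idx = np.arange(n)
    p_t = np.clip(p[idx, labels], _EPS, 1.0)
    one_m = 1.0 - p_t
    loss = float(np.mean(-(one_m**gamma) * np.log(p_t)))
    if gamma == 0.0:
        dldpt_pt = -np.ones(n)  # (dℓ/dp_t)·p_t = −1
    else:
        dldpt = gamma * one_m ** (gamma - 1.0) * np.log(p_t) - one_m**gamma / p_t
        dldpt_pt = dldpt * p_t
    dz = -p * dldpt_pt[:, None]
    dz[idx, labels] += dldpt_pt
    return loss, dz / n


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def recalibrate_batchnorm(model: DVGG, images: np.ndarray, batch_size: int = 64) -> None:
    """Precise-BN: recompute running statistics under the current weights.

    EMA running statistics average activation moments of *past* weights; over
    short runs they lag the final network badly enough to wreck eval-mode
    accuracy.  This pass replaces them with the cumulative moments of the
    given images under the frozen current weights (chunked, train-mode
    normalization within each chunk).
    """
    bns = model._bn_layers()
    if not bns or len(images) < 2:
        return
    saved = [bn.momentum for bn in bns]
    try:
        starts = [s for s in range(0, len(images), batch_size) if len(images) - s >= 2]
        for i, start in enumerate(starts):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)  # running average over chunks
            model.forward(images[start : start + batch_size], train=True)
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m


@dataclass
class TrainResult:
    """Per-epoch history plus the best-held-out-accuracy weight snapshot."""

    history: pd.DataFrame
    best_epoch: int
    best_accuracy: float
    best_state: dict = field(repr=False, default_factory=dict)


def train(
    model: DVGG,
    train_data: tuple[np.ndarray, np.ndarray],
    eval_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> TrainResult:
    """Shuffled mini-batch Adam on focal loss with per-epoch held-out scoring.

    ``train_data``/``eval_data`` are (images NCHW in [−1, 1], integer labels).
    The model is left at its final-epoch weights; the best-accuracy snapshot
    is returned in the result for checkpointing.
    """
    config = config or TrainConfig()
    x_train, y_train = train_data
    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rows = []
    best_acc, best_epoch, best_state = -1.0, -1, {}
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_train)) if config.shuffle else np.arange(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            if len(batch) < 2 and model.config.use_batchnorm:
                continue  # BN train mode needs ≥ 2 samples
            model.zero_grad()
            logits = model.forward(x_train[batch], train=True)
            loss, dz = focal_loss_grad(logits, y_train[batch], config.focal_gamma)
            model.backward(dz)
            opt.step()
            losses.append(loss)
        if model.config.use_batchnorm:
            recalibrate_batchnorm(model, x_train[:512], config.batch_size)
        acc = evaluate(model, eval_data[0], eval_data[1]).overall_accuracy
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "eval_accuracy": acc})
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
    return TrainResult(pd.DataFrame(rows), best_epoch, best_acc, best_state)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class one-vs-rest counts and derived metrics.

    ``per_class`` maps label → dict with TP/TN/FP/FN and ACC/P/S/R/F1;
    ``averaged`` holds the support-weighted means; ``undefined_precision``
    lists classes that received no positive prediction (their P is reported
    as 0).
    """

    labels: list
    confusion: np.ndarray
    per_class: dict
    overall_accuracy: float
    averaged: dict
    macro: dict
    undefined_precision: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class": self.per_class,
            "averaged": self.averaged,
            "macro": self.macro,
            "undefined_precision": list(self.undefined_precision),
        }


def _metrics_from_confusion(confusion: np.ndarray, labels: list) -> MetricsReport:
    n = int(confusion.sum())
    per_class: dict = {}
    undefined = []
    supports, ks = [], {"precision": [], "specificity": [], "recall": [], "f1": []}
    for i, label in enumerate(labels):
        tp = int(confusion[i, i])
        fn = int(confusion[i].sum() - tp)
        fp = int(confusion[:, i].sum() - tp)
        tn = n - tp - fn - fp
        if tp + fp == 0:
            undefined.append(label)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        s = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        per_class[label] = {
            "TP": tp, "TN": tn, "FP": fp, "FN": fn,
            "ACC": (tp + tn) / n, "P": p, "S": s, "R": r, "F1": f1,
        }
        supports.append(tp + fn)
        for key, val in zip(ks, (p, s, r, f1)):
            ks[key].append(val)
    supports_arr = np.asarray(supports, dtype=np.float64)
    weights = supports_arr / supports_arr.sum() if supports_arr.sum() else supports_arr
    averaged = {k: float(np.dot(weights, v)) for k, v in ks.items()}
    macro = {k: float(np.mean(v)) for k, v in ks.items()}
    overall = float(np.trace(confusion) / n)
    return MetricsReport(list(labels), confusion, per_class, overall, averaged, macro, undefined)


def metrics_from_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    label_names: list,
) -> MetricsReport:
    """One-vs-rest metrics from integer true/predicted label vectors."""
    y_true = np.asarray(y_true, dtype=np.intp)
    y_pred = np.asarray(y_pred, dtype=np.intp)
    k = len(label_names)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (y_true, y_pred), 1)
    return _metrics_from_confusion(confusion, list(label_names))


def evaluate(
    model: DVGG,
    images: np.ndarray,
    labels: np.ndarray,
    label_names: list | None = None,
    batch_size: int = 64,
) -> MetricsReport:
    """Argmax predictions → confusion matrix → per-class and averaged metrics."""
    labels = np.asarray(labels, dtype=np.intp)
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    preds = []
    for start in range(0, len(images), batch_size):
        probs = model.predict_proba(images[start : start + batch_size])
        preds.append(probs.argmax(axis=1))
    pred = np.concatenate(preds)
    n_classes = model.config.num_classes
    names = list(label_names) if label_names is not None else list(range(n_classes))
    return metrics_from_predictions(labels, pred, names)


# ---------------------------------------------------------------------------
# inference plumbing
# ---------------------------------------------------------------------------

def load_images(
    manifest: pd.DataFrame,
    target: int = 224,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Read manifest images, resize, normalize, return (NCHW array, labels, names)."""
    names = sorted(manifest["label"].unique())
    index = {name: i for i, name in enumerate(names)}
    xs, ys = [], []
    for row in manifest.itertuples(index=False):
        arr = np.asarray(Image.open(row.path).convert("RGB"))
        arr = resize_bicubic(arr, target)
        xs.append(normalize_for_model(arr).transpose(2, 0, 1))
        ys.append(index[row.label])
    return np.stack(xs), np.asarray(ys, dtype=np.intp), names


def predict(
    model: DVGG,
    paths: list[str | Path],
    label_names: list | None = None,
    seg_config: OOAConfig | None = None,
    segment: bool = True,
) -> list[dict]:
    """Full-pipeline inference: segment → resize → normalize → forward.

    Unreadable images yield a per-file ``error`` entry; the batch continues.
    """
    target = model.config.input_size
    names = label_names or list(range(model.config.num_classes))
    results = []
    for path in paths:
        try:
            arr = np.asarray(Image.open(path).convert("RGB"))
            if segment:
                arr, _, _ = segment_mushroom(arr, seg_config)
            arr = resize_bicubic(arr, target)
            x = normalize_for_model(arr).transpose(2, 0, 1)[None]
            probs = model.predict_proba(x)[0]
            results.append(
                {
                    "path": str(path),
                    "label": names[int(probs.argmax())],
                    "probabilities": {names[i]: float(p) for i, p in enumerate(probs)},
                }
            )
        except (OSError, ValueError) as exc:
            results.append({"path": str(path), "error": str(exc)})
    return results
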