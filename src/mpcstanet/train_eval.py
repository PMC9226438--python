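"""Training loop and evaluation protocol for the stage classifier.

Training follows the published settings: mini-batch size 32 (8 at
evaluation), learning rate 1e-3, Adam with its canonical defaults,
cross-entropy loss.  The published schedule runs 140 epochs on the real
collection; the desk default here is 5 epochs on phantom fixtures.

Evaluation reports the 4×4 confusion matrix (rows = true class, columns
= predicted, class order ND=0, VMD=1, MD=2, MOD=3), per-class recall /
precision / F1, overall accuracy, and macro mAP — the macro mean over
classes of one-vs-rest average precision computed from softmax scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, confusion_matrix

from ._engine import Adam, Module, Tensor, softmax_cross_entropy
from .synthetic_fixtures import CLASS_INDEX, CLASS_LABELS, LabeledImageSet

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "TrainingDivergedError",
    "MetricsReport",
    "records_to_arrays",
    "train",
    "predict_scores",
    "compute_metrics",
    "evaluate",
]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class TrainConfig:
    batch_size_train: int = 32
    batch_size_eval: int = 8
    learning_rate: float = 1e-3
    epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.batch_size_train < 1 or self.batch_size_eval < 1:
            raise ValueError("batch sizes must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainingHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def records_to_arrays(dataset: LabeledImageSet | list) -> tuple[np.ndarray, np.ndarray]:
    """Images to normalised NCHW float32 batches and integer labels.

    Grayscale pixels are scaled to [-1, 1] and replicated to 3 channels
    so the canonical 3-channel stem (and its parameter count) applies.
    """
    records = dataset.records if isinstance(dataset, LabeledImageSet) else list(dataset)
    if not records:
        raise ValueError("empty dataset")
    x = np.stack([r.pixels for r in records]).astype(np.float32)
    x = (x / 255.0 - 0.5) / 0.5
    x = np.repeat(x[:, None], 3, axis=1)
    y = np.array([CLASS_INDEX[r.label] for r in records], dtype=np.int64)
    return x, y


def train(model: Module, train_set: LabeledImageSet, config: TrainConfig,
          eval_set: LabeledImageSet | None = None,
          stop_at_val_accuracy: float | None = None) -> tuple[Module, TrainingHistory]:
    """Mini-batch optimisation with Adam and cross-entropy.

    Fully seeded: epoch shuffles come from ``config.seed``.  With
    ``eval_set`` the held-out accuracy is recorded per epoch, and
    ``stop_at_val_accuracy`` ends training once it is reached.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    x_all, y_all = records_to_arrays(train_set)
    n = len(y_all)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(list(model.parameters()), lr=config.learning_rate)
    history = TrainingHistory()
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size_train):
            batch = order[start:start + config.batch_size_train]
            xb = Tensor(x_all[batch])
            yb = y_all[batch]
            logits = model(xb)
            loss = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss {loss.data!r} at epoch {epoch}, step {start}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        history.epoch_loss.append(float(np.mean(losses)))
        history.epoch_accuracy.append(correct / n)
        msg = (f"epoch {epoch + 1}/{config.epochs}: "
               f"loss {history.epoch_loss[-1]:.4f} acc {history.epoch_accuracy[-1]:.3f}")
        if eval_set is not None:
            scores = predict_scores(model, eval_set, batch_size=config.batch_size_eval)
            _, y_val = records_to_arrays(eval_set)
            val_acc = float((scores.argmax(axis=1) == y_val).mean())
            history.val_accuracy.append(val_acc)
            msg += f" val_acc {val_acc:.3f}"
        logger.info(msg)
        if (stop_at_val_accuracy is not None and history.val_accuracy
                and history.val_accuracy[-1] >= stop_at_val_accuracy):
            break
    return model, history


def predict_scores(model: Module, images, batch_size: int = 8) -> np.ndarray:
    """Per-class softmax scores, one row per image (rows sum to 1)."""
    if isinstance(images, LabeledImageSet) or (
        isinstance(images, list) and images and hasattr(images[0], "pixels")
    ):
        x, _ = records_to_arrays(images)
    else:
        x = np.asarray(images, dtype=np.float32)
    model.eval()
    rows = []
    for start in range(0, len(x), batch_size):
        logits = model(Tensor(x[start:start + batch_size])).data
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        rows.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(rows, axis=0)


@dataclass
class MetricsReport:
    """Per-class and overall evaluation metrics.

    Class order is fixed (ND=0, VMD=1, MD=2, MOD=3); the confusion
    matrix rows are true classes, columns predictions.
    """

    confusion: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_map: float

    def to_dict(self) -> dict:
        return {
            "class_order": list(CLASS_LABELS),
            "confusion_matrix": self.confusion.tolist(),
            "recall": self.recall.tolist(),
            "precision": self.precision.tolist(),
            "f1": self.f1.tolist(),
            "accuracy": self.accuracy,
            "macro_map": self.macro_map,
        }


def compute_metrics(truth, scores) -> MetricsReport:
    """Metrics from integer truth labels and a (n, 4) score matrix.

    Argmax predictions fill the confusion matrix; per-class precision,
    recall and F1 come from it (0 where undefined, with a logged
    warning).  Macro mAP averages one-vs-rest average precision over the
    classes present in the truth.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=np.float64)
    if truth.ndim != 1 or scores.ndim != 2 or len(truth) != len(scores):
        raise ValueError(
            f"length mismatch: {len(truth)} labels vs scores shape {scores.shape}"
        )
    k = len(CLASS_LABELS)
    preds = scores.argmax(axis=1)
    cm = confusion_matrix(truth, preds, labels=list(range(k)))
    tp = np.diag(cm).astype(np.float64)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    if np.any(tp + fn == 0) or np.any(tp + fp == 0):
        logger.warning("some per-class metrics undefined (empty class); reported as 0")
    aps = []
    for c in range(k):
        pos = truth == c
        if pos.any():
            aps.append(average_precision_score(pos.astype(int), scores[:, c]))
    accuracy = float(tp.sum() / cm.sum()) if cm.sum() else 0.0
    return MetricsReport(cm, recall, precision, f1, accuracy, float(np.mean(aps)))


def evaluate(model: Module, dataset: LabeledImageSet,
             batch_size: int = 8) -> MetricsReport:
    """Score a dataset in manifest order and compute the metrics report."""
    scores = predict_scores(model, dataset, batch_size=batch_size)
    _, truth = records_to_arrays(dataset)
    return compute_metrics(truth, scores)
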