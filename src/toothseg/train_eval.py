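"""Training loop and segmentation metrics.

Training minimizes the mean per-face cross-entropy with Adam, the
learning rate halving on a fixed epoch schedule.  Evaluation reports
overall accuracy, per-class recall ("accuracy"), intersection-over-union
(Jaccard) and Dice, plus a table where the left and right tooth of the
same type are pooled (counts summed before ratios), mirroring how
per-tooth-type results are conventionally reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor
from .errors import ConfigError, DataError, LabelError
from .mesh_io import FaceFeatureMatrix, N_CLASSES
from .neighborhood import knn_graph
from .network import NeighborIndex, SegmentationModel

__all__ = ["TrainConfig", "MetricReport", "Adam", "lr_at_epoch", "train",
           "evaluate", "AGGREGATION_GROUPS"]

# Table rows pooling left/right FDI pairs: positional classes c and c+8
# are the same tooth type in opposite quadrants.
AGGREGATION_GROUPS: dict[str, tuple[int, ...]] = {
    "gum": (0,),
    "3rd M": (8, 16), "2nd M": (7, 15), "1st M": (6, 14),
    "2nd PM": (5, 13), "1st PM": (4, 12), "C": (3, 11),
    "LI": (2, 10), "CI": (1, 9),
}


@dataclass
class TrainConfig:
    """Optimization hyperparameters (published defaults)."""

    epochs: int = 100
    lr: float = 1e-3
    lr_decay: float = 0.5
    lr_step_epochs: int = 30
    batch_size: int = 4
    max_steps: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ConfigError("lr must be >= 0")
        if not 0 < self.lr_decay <= 1:
            raise ConfigError("lr_decay must be in (0, 1]")
        if self.epochs < 1 or self.lr_step_epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs, lr_step_epochs, batch_size must be "
                              ">= 1")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Stepwise-decayed learning rate at a given epoch."""
    return config.lr * config.lr_decay ** (epoch // config.lr_step_epochs)


class Adam:
    """Adaptive-moment optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _prepare_dataset(model: SegmentationModel, dataset):
    """Normalize dataset entries to (features, labels, dilated indices),
    precomputing the static indices once where absent."""
    if not dataset:
        raise DataError("empty dataset")
    prepared = []
    for entry in dataset:
        feats, labels = entry[0], np.asarray(entry[1], dtype=np.int64)
        indices = entry[2] if len(entry) > 2 and entry[2] is not None \
            else model.compute_dilated_indices(feats.centers)
        if len(labels) != feats.n_faces:
            raise DataError("labels do not match face count")
        if labels.size and (labels.min() < 0
                            or labels.max() >= model.config.n_classes):
            raise LabelError("label outside the configured class space")
        cfg = model.config
        # the input-space kNN graph is fixed per mesh: compute it once
        graph0 = (knn_graph(feats.values, cfg.local_k)
                  if cfg.local_widths and not cfg.split_streams else None)
        prepared.append((feats, labels, indices, graph0))
    return prepared


def train(model: SegmentationModel, dataset, config: TrainConfig):
    """Train in place; returns (model, log).

    ``dataset`` is a list of (FaceFeatureMatrix, labels[, dilated
    indices]) tuples.  One optimizer step consumes up to ``batch_size``
    meshes (gradients averaged).  Fully seeded: data order and any
    dropout derive from ``config.seed``, so one seed gives one loss
    curve.
    """
    prepared = _prepare_dataset(model, dataset)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters())
    log: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(len(prepared))
        epoch_losses, correct, total = [], 0, 0
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo:lo + config.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for i in batch:
                feats, labels, indices, graph0 = prepared[i]
                logits = model.forward_tensors(Tensor(feats.values),
                                               indices, training=True,
                                               input_graph=graph0)
                loss = logits.cross_entropy(labels)
                loss.backward(np.array(1.0 / len(batch)))
                batch_loss += float(loss.data) / len(batch)
                pred = np.argmax(logits.data, axis=1)
                correct += int((pred == labels).sum())
                total += len(labels)
            opt.step(lr)
            step += 1
            epoch_losses.append(batch_loss)
            log.append({"epoch": epoch, "step": step, "lr": lr,
                        "loss": batch_loss})
            if config.max_steps is not None and step >= config.max_steps:
                log[-1]["train_oa"] = correct / max(total, 1)
                return model, log
        log[-1]["train_oa"] = correct / max(total, 1)
        log[-1]["epoch_loss"] = float(np.mean(epoch_losses))
    return model, log


def write_log_jsonl(log: list[dict], path) -> None:
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricReport:
    """Overall and per-class segmentation metrics.

    ``per_class`` columns: class, accuracy (recall), iou, dice, support.
    ``aggregated`` pools left/right FDI pairs (17-class tasks only).
    """

    overall_accuracy: float
    mean_iou: float
    mean_dice: float
    per_class: pd.DataFrame
    aggregated: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        table = self.per_class.copy()
        table.insert(0, "scope", "per_class")
        if self.aggregated is not None:
            agg = self.aggregated.copy()
            agg.insert(0, "scope", "aggregated")
            agg = agg.rename(columns={"group": "class"})
            table = pd.concat([table, agg], ignore_index=True)
        summary = pd.DataFrame([{
            "scope": "overall", "class": "OA",
            "accuracy": self.overall_accuracy, "iou": self.mean_iou,
            "dice": self.mean_dice, "support": int(
                self.per_class["support"].sum()),
        }])
        pd.concat([table, summary], ignore_index=True).to_csv(path,
                                                              index=False)


def _metrics_from_counts(tp, fp, fn):
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        iou = np.where(tp + fp + fn > 0, tp / (tp + fp + fn), np.nan)
        dice = np.where(2 * tp + fp + fn > 0,
                        2 * tp / (2 * tp + fp + fn), np.nan)
    return acc, iou, dice


def evaluate(predictions, truth, class_count: int = N_CLASSES,
             include_absent: bool = False) -> MetricReport:
    """Per-class accuracy/IoU/Dice and their means.

    Classes absent from both truth and prediction are excluded from the
    means (set ``include_absent`` to count them as 0).  Per-class
    accuracy is recall: TP / (TP + FN).
    """
    predictions = np.asarray(predictions, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predictions.shape != truth.shape:
        raise DataError("predictions and truth differ in length")
    if predictions.size == 0:
        raise DataError("empty label arrays")
    for name, arr in (("predictions", predictions), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= class_count:
            raise LabelError(f"{name} outside 0..{class_count - 1}")

    confusion = np.bincount(truth * class_count + predictions,
                            minlength=class_count * class_count
                            ).reshape(class_count, class_count).astype(float)
    tp = np.diag(confusion)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    acc, iou, dice = _metrics_from_counts(tp, fp, fn)
    present = (tp + fp + fn) > 0
    support = confusion.sum(axis=1).astype(int)

    per_class = pd.DataFrame({
        "class": np.arange(class_count),
        "accuracy": acc, "iou": iou, "dice": dice, "support": support,
    })
    if include_absent:
        sel = np.ones(class_count, dtype=bool)
        iou_m = np.where(present, iou, 0.0)
        dice_m = np.where(present, dice, 0.0)
    else:
        sel = present
        iou_m, dice_m = iou, dice
    mean_iou = float(np.nanmean(np.where(sel, iou_m, np.nan)))
    mean_dice = float(np.nanmean(np.where(sel, dice_m, np.nan)))
    overall = float(tp.sum() / confusion.sum())

    aggregated = None
    if class_count == N_CLASSES:
        rows = []
        for name, members in AGGREGATION_GROUPS.items():
            members = [m for m in members if m < class_count]
            gtp = tp[members].sum()
            gfp = fp[members].sum()
            gfn = fn[members].sum()
            a, i, d = _metrics_from_counts(
                np.array([gtp]), np.array([gfp]), np.array([gfn]))
            rows.append({"group": name, "accuracy": a[0], "iou": i[0],
                         "dice": d[0],
                         "support": int(support[members].sum())})
        aggregated = pd.DataFrame(rows)

    return MetricReport(overall_accuracy=overall, mean_iou=mean_iou,
                        mean_dice=mean_dice, per_class=per_class,
                        aggregated=aggregated)
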