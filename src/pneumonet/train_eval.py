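"""Training loop, evaluation, and the ablation runner.

The optimization recipe mirrors the emulated study: mini-batch AdamW
(decoupled weight decay, first-moment coefficient beta1 = 0.9), a step
learning-rate schedule multiplying the rate by ``lr_gamma`` every
``lr_step`` epochs, and a fixed epoch budget with no early stopping.
Defaults are the full-scale recipe (batch 16, lr 5e-5, weight decay 1e-4,
x0.1 every 5 epochs, 100 epochs); :data:`DESK_TRAIN_CONFIG` is the
CPU-scale preset used with the synthetic phantoms.

Everything is seeded: parameter initialization, data order, and the
synthetic data itself, so (config, seed) -> TrainingHistory is reproducible
bit-for-bit on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import AdamW, softmax
from . import losses as L
from .metrics import MetricsReport, compute_report
from .model_zoo import (
    DESK_CONFIG,
    ImageClassifier,
    NetworkConfig,
    build_attention_net,
    build_resnet_baseline,
)
from .synthetic_xray import (
    DESK_SPEC,
    ImageSample,
    PhantomSpec,
    generate_dataset,
    split_dataset,
)

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "DESK_TRAIN_CONFIG",
    "lr_at_epoch",
    "train",
    "evaluate",
    "run_ablation",
    "ABLATION_VARIANTS",
    "samples_to_arrays",
]


class TrainError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe; defaults are the full-scale settings."""

    batch_size: int = 16
    lr0: float = 5e-5
    beta1: float = 0.9
    weight_decay: float = 1e-4
    lr_step: int = 5
    lr_gamma: float = 0.1
    max_epochs: int = 100
    seed: int = 0
    loss_name: str = "cross_entropy"
    loss_alpha: float = 0.25
    loss_gamma: float = 2.0
    count_mapping: str = "per_class"
    device: str = "cpu"

    def validate(self) -> None:
        if self.batch_size < 1:
            raise TrainError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.lr0 <= 0:
            raise TrainError(f"lr0 must be > 0, got {self.lr0}")
        if not 0.0 < self.lr_gamma <= 1.0:
            raise TrainError(f"lr_gamma must be in (0,1], got {self.lr_gamma}")
        if not 0.0 <= self.beta1 < 1.0:
            raise TrainError(f"beta1 must be in [0,1), got {self.beta1}")
        if self.weight_decay < 0:
            raise TrainError("weight_decay must be >= 0")
        if self.lr_step < 1 or self.max_epochs < 1:
            raise TrainError("lr_step and max_epochs must be >= 1")
        if self.loss_name not in ("cross_entropy", "focal", "modified_focal"):
            raise TrainError(f"unknown loss {self.loss_name!r}")


#: CPU-scale recipe for the 64x64 synthetic phantoms: a from-scratch
#: 10-epoch run needs a larger initial rate than the 100-epoch full-scale
#: recipe; the step schedule shape (x0.1 every 5 epochs) is kept.
DESK_TRAIN_CONFIG = TrainConfig(lr0=3e-3, max_epochs=6, lr_step=5,
                                lr_gamma=0.1)


@dataclass
class TrainingHistory:
    """Per-epoch training-loss / validation-accuracy / learning-rate trace."""

    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def append(self, epoch: int, train_loss: float, val_accuracy: float,
               lr: float) -> None:
        self.epochs.append(epoch)
        self.train_loss.append(train_loss)
        self.val_accuracy.append(val_accuracy)
        self.lr.append(lr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "train_loss": self.train_loss,
                             "val_accuracy": self.val_accuracy, "lr": self.lr})


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step schedule: lr0 * lr_gamma ** floor(epoch / lr_step)."""
    if epoch < 0:
        raise TrainError(f"epoch must be >= 0, got {epoch}")
    return config.lr0 * config.lr_gamma ** (epoch // config.lr_step)


def samples_to_arrays(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into an NCHW float32 batch and an int label vector."""
    if not samples:
        raise TrainError("empty sample list")
    imgs = []
    for s in samples:
        px = s.pixels
        if px.ndim == 2:
            px = px[None, :, :]
        else:  # HWC -> CHW
            px = px.transpose(2, 0, 1)
        imgs.append(px.astype(np.float32))
    x = np.stack(imgs)
    y = np.array([s.label for s in samples], dtype=int)
    return x, y


def _loss_and_grad(logits: np.ndarray, y: np.ndarray,
                   config: TrainConfig, loss_cfg: L.LossConfig | None):
    """Mean loss over the batch and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64), axis=1)
    yp = probs[:, 1]
    batch = L.PredictionBatch(yp, y)
    if config.loss_name == "cross_entropy":
        loss = L.cross_entropy(batch)
        dyp = L.cross_entropy_grad(batch)
    elif config.loss_name == "focal":
        loss = L.focal_loss(batch, alpha_t=config.loss_alpha,
                            gamma=config.loss_gamma)
        dyp = L.focal_loss_grad(batch, alpha_t=config.loss_alpha,
                                gamma=config.loss_gamma)
    else:
        loss = L.modified_focal_loss(batch, loss_cfg)
        dyp = L.modified_focal_loss_grad(batch, loss_cfg)
    n = len(y)
    # chain through softmax: d yp / d z1 = yp(1-yp), d yp / d z0 = -yp(1-yp)
    dz1 = dyp * yp * (1.0 - yp) / n
    dlogits = np.stack([-dz1, dz1], axis=1).astype(np.float32)
    return float(loss), dlogits


def train(model: ImageClassifier, train_set: list[ImageSample],
          val_set: list[ImageSample], config: TrainConfig,
          ) -> tuple[ImageClassifier, TrainingHistory]:
    """Mini-batch AdamW training with the step lr schedule.

    Records mean train loss and full-validation accuracy at every epoch end.
    Aborts with a diagnostic if a batch produces a non-finite loss.
    """
    config.validate()
    if not train_set or not val_set:
        raise TrainError("train and validation sets must be non-empty")
    x_train, y_train = samples_to_arrays(train_set)
    x_val, y_val = samples_to_arrays(val_set)
    loss_cfg = None
    if config.loss_name == "modified_focal":
        loss_cfg = L.LossConfig(
            alpha=config.loss_alpha, gamma=config.loss_gamma,
            n_normal=max(1, int((y_train == 0).sum())),
            n_pneumonia=max(1, int((y_train == 1).sum())),
            count_mapping=config.count_mapping)
    opt = AdamW(model.params(), lr=config.lr0, beta1=config.beta1,
                weight_decay=config.weight_decay)
    history = TrainingHistory()
    order_rng = np.random.default_rng(config.seed)
    n = len(y_train)
    for epoch in range(config.max_epochs):
        opt.lr = lr_at_epoch(config, epoch)
        order = order_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x_train[idx], training=True)
            loss, dlogits = _loss_and_grad(logits, y_train[idx], config, loss_cfg)
            if not np.isfinite(loss):
                raise TrainError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss)
        val_acc = float(np.mean(_predict(model, x_val) == y_val))
        history.append(epoch, float(np.mean(epoch_losses)), val_acc, opt.lr)
    return model, history


def _predict(model: ImageClassifier, x: np.ndarray,
             batch_size: int = 64) -> np.ndarray:
    preds = []
    for start in range(0, len(x), batch_size):
        preds.append(model.predict(x[start:start + batch_size]))
    return np.concatenate(preds)


def evaluate(model: ImageClassifier, dataset: list[ImageSample]) -> MetricsReport:
    """Argmax over the two logits per sample -> confusion matrix -> metrics."""
    if not dataset:
        raise TrainError("empty evaluation dataset")
    x, y = samples_to_arrays(dataset)
    y_pred = _predict(model, x)
    return compute_report(y, y_pred)


#: ablation rows: (name, model builder, loss)
ABLATION_VARIANTS = (
    ("baseline", build_resnet_baseline, "cross_entropy"),
    ("side_branch", build_attention_net, "cross_entropy"),
    ("side_branch_focal", build_attention_net, "modified_focal"),
)


def run_ablation(dataset_spec: PhantomSpec = DESK_SPEC,
                 base_config: TrainConfig = DESK_TRAIN_CONFIG,
                 net_config: NetworkConfig = DESK_CONFIG,
                 seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                 train_counts: tuple[int, int] = (210, 80),
                 val_counts: tuple[int, int] = (60, 20),
                 ) -> pd.DataFrame:
    """Train the three variants on identical per-seed datasets.

    Variants: (a) residual baseline + cross-entropy, (b) + side-branch
    attention blocks, (c) + side-branch blocks + modified focal loss. Returns
    one row per (variant, seed) with all metrics; aggregate with
    :func:`summarize_ablation`.
    """
    rows = []
    for seed in seeds:
        spec = replace(dataset_spec, seed=int(seed))
        samples, _ = generate_dataset(spec)
        train_set, val_set = split_dataset(samples, train_counts, val_counts,
                                           seed=int(seed))
        for name, builder, loss_name in ABLATION_VARIANTS:
            model = builder(net_config, seed=int(seed))
            cfg = replace(base_config, seed=int(seed), loss_name=loss_name)
            model, _hist = train(model, train_set, val_set, cfg)
            report = evaluate(model, val_set)
            row = {"variant": name, "seed": int(seed), **report.to_dict()}
            # minority-class recall: the normal class is the rarer one
            row["minority_recall"] = report.specificity
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Per-variant mean/sd/median of every metric, preserving row order."""
    metric_cols = ["accuracy", "precision", "recall", "specificity", "f1",
                   "minority_recall"]
    out = table.groupby("variant", sort=False)[metric_cols].agg(
        ["mean", "std", "median"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()
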