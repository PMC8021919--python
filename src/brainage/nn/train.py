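"""SGD training loop with the step learning-rate schedule and per-epoch
checkpoint records.

Optimization follows the standard heavy-ball recipe: SGD with momentum 0.9,
weight decay 5e-4 folded into the gradient, initial learning rate 0.1, decayed
by a factor of 10 once half and again once three quarters of the epochs have
elapsed.  After every epoch the model is evaluated on the validation split and
a :class:`CheckpointRecord` stores the validation MAE and the Spearman
correlation of the brain-age delta with age — the two quantities the
checkpoint-selection rules downstream filter on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ..evaluation import PredictionBatch
from .losses import LOSS_MODES, composite_loss, composite_loss_grad
from .resnet import ResNet26


@dataclass
class TrainConfig:
    lr: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 0.0005
    epochs: int = 300
    batch_size: int = 8
    lr_decay_factor: float = 10.0
    decay_milestones: tuple[float, float] = (0.5, 0.75)
    loss_mode: str = "plain"
    reg_weight: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates, batch size and epochs must be positive")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")


@dataclass
class CheckpointRecord:
    """One epoch's saved state with its validation metrics."""

    config_id: str
    epoch: int
    val_mae: float
    val_rho: float
    weights: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.val_mae < 0:
            raise ValueError("val_mae must be non-negative")
        if not -1.0 <= self.val_rho <= 1.0:
            raise ValueError("val_rho must lie in [-1, 1]")


class SGD:
    """Momentum SGD with (coupled) L2 weight decay."""

    def __init__(self, model: ResNet26, config: TrainConfig) -> None:
        self.model = model
        self.momentum = config.momentum
        self.weight_decay = config.weight_decay
        self.lr = config.lr
        self._velocity = {
            f"{name}.{k}": np.zeros_like(v)
            for name, params, _ in model.parameters()
            for k, v in params.items()
        }

    def step(self) -> None:
        for name, params, grads in self.model.parameters():
            for k in params:
                g = grads[k] + self.weight_decay * params[k]
                v = self._velocity[f"{name}.{k}"]
                v *= self.momentum
                v += g
                params[k] -= self.lr * v


def lr_schedule(config: TrainConfig) -> np.ndarray:
    """Per-epoch learning rate: x(1/factor) at each milestone fraction."""
    lrs = np.full(config.epochs, config.lr)
    for frac in config.decay_milestones:
        lrs[np.arange(config.epochs) >= frac * config.epochs] /= config.lr_decay_factor
    return lrs


def _val_metrics(
    model: ResNet26, val_x: np.ndarray, val_y: np.ndarray, val_sex: np.ndarray | None
) -> tuple[float, float]:
    preds = model.predict(val_x, sex=val_sex)
    mae = float(np.mean(np.abs(preds - val_y)))
    delta = preds - val_y
    if np.ptp(delta) == 0 or np.ptp(val_y) == 0:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(delta, val_y).statistic)
    return mae, rho


def train(
    model: ResNet26,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig,
    train_sex: np.ndarray | None = None,
    val_sex: np.ndarray | None = None,
    config_id: str = "model",
    keep_weights: bool = True,
) -> list[CheckpointRecord]:
    """Train and return one checkpoint record per epoch.

    ``keep_weights`` stores a copy of the full parameter state in every
    record (fine at desk scale; switch off for long runs where only the
    metrics are needed for selection).
    """
    n = train_x.shape[0]
    if config.batch_size > n:
        raise ValueError("batch_size exceeds the training set size")
    rng = np.random.default_rng(config.seed)
    optimizer = SGD(model, config)
    lrs = lr_schedule(config)
    records: list[CheckpointRecord] = []
    for epoch in range(config.epochs):
        optimizer.lr = float(lrs[epoch])
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            sb = None if train_sex is None else train_sex[idx]
            model.zero_grad()
            preds = model.forward(xb, sex=sb, training=True)
            batch = PredictionBatch(y=yb, y_pred=preds)
            loss = composite_loss(batch, config.loss_mode, config.reg_weight)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            dpred = composite_loss_grad(batch, config.loss_mode, config.reg_weight)
            model.backward(dpred)
            optimizer.step()
        val_mae, val_rho = _val_metrics(model, val_x, val_y, val_sex)
        records.append(
            CheckpointRecord(
                config_id=config_id,
                epoch=epoch,
                val_mae=val_mae,
                val_rho=val_rho,
                weights=model.state_dict() if keep_weights else None,
            )
        )
    return records


def best_checkpoint(records: list[CheckpointRecord]) -> CheckpointRecord:
    """The record with the smallest validation MAE (earliest epoch on ties)."""
    if not records:
        raise ValueError("no checkpoint records")
    return min(records, key=lambda r: (r.val_mae, r.epoch))
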