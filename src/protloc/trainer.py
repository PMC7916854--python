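"""Training protocol: splits, loss, Adam schedule, early stopping.

The protocol is identical for both network variants: Adam with the
standard defaults (lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8), mean
binary cross-entropy over all sigmoid outputs, learning rate divided by
3 when the validation loss has not improved on its running best for 8
consecutive epochs, and early stopping after 20 epochs without
improvement.  The split is deterministic and index-based: the first
``train_count`` samples form the training block, the last 10% of that
block is held out for validation, and the remainder of the dataset is
the test set.

Two stagnation counters are kept: the plateau counter resets both on
improvement and after a learning-rate drop (so drops happen at the 8th,
16th, ... stagnant epoch), while the early-stopping counter resets only
on improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nets import Model
from .nn import Adam, BatchNorm2d, bce_grad, binary_cross_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainState",
    "TrainData",
    "split_dataset",
    "loss",
    "lr_schedule_step",
    "early_stop_check",
    "train",
    "save_history",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1.0e-8
    batch_size: int = 64
    max_epochs: int = 100
    plateau_patience: int = 8
    plateau_factor: float = 3.0
    early_stop_patience: int = 20
    val_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be positive")


@dataclass
class TrainState:
    epoch: int = 0
    current_lr: float = 0.001
    best_val_loss: float = np.inf
    epochs_since_improvement: int = 0
    plateau_counter: int = 0
    history: list[dict] = field(default_factory=list)


@dataclass
class TrainData:
    """Arrays plus the index-based split used for one training run."""

    images: np.ndarray     # (n, 4, S, S)
    targets: np.ndarray    # (n, 13) for CNN; (n, 13, out, out) for FCN
    train_ids: np.ndarray
    val_ids: np.ndarray


def split_dataset(
    n_total: int, train_count: int, val_fraction: float = 0.10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic index-based split into (train, val, test).

    The first ``train_count`` indices are the training block; the last
    ``val_fraction`` of that block becomes validation; everything after
    the block is test.
    """
    if train_count > n_total:
        raise ValueError("train_count exceeds n_total")
    n_val = int(round(train_count * val_fraction))
    if n_val < 1:
        raise ValueError("val_fraction yields an empty validation set")
    if n_val >= train_count:
        raise ValueError("val_fraction leaves no training samples")
    train_ids = np.arange(0, train_count - n_val)
    val_ids = np.arange(train_count - n_val, train_count)
    test_ids = np.arange(train_count, n_total)
    return train_ids, val_ids, test_ids


def loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all output elements."""
    return binary_cross_entropy(predictions, targets)


def lr_schedule_step(
    state: TrainState,
    new_val_loss: float,
    patience: int = 8,
    factor: float = 3.0,
) -> TrainState:
    """Plateau schedule: divide lr by ``factor`` after ``patience`` stagnant epochs.

    Improvement means strictly beating the running best validation loss.
    The plateau counter resets after a drop; the early-stopping counter
    does not.
    """
    if new_val_loss < state.best_val_loss:
        state.best_val_loss = new_val_loss
        state.epochs_since_improvement = 0
        state.plateau_counter = 0
    else:
        state.epochs_since_improvement += 1
        state.plateau_counter += 1
        if state.plateau_counter >= patience:
            state.current_lr /= factor
            state.plateau_counter = 0
    return state


def early_stop_check(state: TrainState, patience: int = 20) -> bool:
    """True iff the validation loss has been stagnant for ``patience`` epochs."""
    return state.epochs_since_improvement >= patience


def _forward_batched(model: Model, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    outs = [model.forward(x[i : i + chunk], train=False) for i in range(0, len(x), chunk)]
    return np.concatenate(outs, axis=0)


def _snapshot(model: Model) -> dict:
    return {
        "params": [p.value.copy() for p in model.params()],
        "bn": [
            (layer.running_mean.copy(), layer.running_var.copy())
            for layer in model.net
            if isinstance(layer, BatchNorm2d)
        ],
    }


def _restore(model: Model, snap: dict) -> None:
    for p, v in zip(model.params(), snap["params"]):
        p.value[...] = v
    bns = [l for l in model.net if isinstance(l, BatchNorm2d)]
    for layer, (mean, var) in zip(bns, snap["bn"]):
        layer.running_mean = mean.copy()
        layer.running_var = var.copy()


def train(model: Model, data: TrainData, config: TrainConfig) -> tuple[Model, TrainState]:
    """Fit ``model`` on ``data`` under the standard protocol.

    Returns the model restored to its best-validation weights, plus the
    training state with the per-epoch history.  Fully seeded: two runs
    with the same seed and data produce identical histories.
    """
    config.validate()
    if len(data.train_ids) == 0:
        raise ValueError("empty training set")
    state = TrainState(current_lr=config.learning_rate)
    if config.max_epochs == 0:
        return model, state

    opt = Adam(
        model.params(),
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        epsilon=config.epsilon,
    )
    rng = np.random.default_rng(config.seed)
    best = _snapshot(model)

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(data.train_ids)
        total, count = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = data.images[idx], data.targets[idx]
            opt.lr = state.current_lr
            out = model.forward(xb, train=True)
            total += binary_cross_entropy(out, yb) * len(idx)
            count += len(idx)
            model.net.backward(bce_grad(out, yb))
            opt.step()
            opt.zero_grad()
        train_loss = total / count

        val_out = _forward_batched(model, data.images[data.val_ids])
        val_loss = binary_cross_entropy(val_out, data.targets[data.val_ids])

        improved = val_loss < state.best_val_loss
        state = lr_schedule_step(
            state, val_loss, patience=config.plateau_patience, factor=config.plateau_factor
        )
        if improved:
            best = _snapshot(model)
        state.epoch = epoch
        state.history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": state.current_lr}
        )
        logger.info(
            "epoch %d: train %.4f val %.4f lr %.2e", epoch, train_loss, val_loss, state.current_lr
        )
        if early_stop_check(state, patience=config.early_stop_patience):
            logger.info("early stopping at epoch %d", epoch)
            break

    _restore(model, best)
    return model, state


def save_history(state: TrainState, path: str | Path) -> None:
    """Write the per-epoch loss curve as CSV (epoch, train_loss, val_loss, lr)."""
    pd.DataFrame(state.history, columns=["epoch", "train_loss", "val_loss", "lr"]).to_csv(
        path, index=False, lineterminator="\n"
    )
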