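"""SD-ResNet optimization.

The schedule follows the recipe the model was designed with: AdamW with
decoupled weight decay; a 5-epoch linear warm-up followed by cosine
annealing to the final epoch; an exponential moving average of the weights
(decay 0.992) used for validation inference; encoder batch-norm layers
frozen to their running statistics (small-batch stabilization); a gated
checkpointing strategy that records the best validation model only after
epoch 21; and early stopping when the validation loss fails to improve
(relative reduction > 1e-4) for more than ``patience`` consecutive epochs.
A last-epoch checkpoint is always kept.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from srcorrect.dataset import (
    TrainingPair,
    augment_flip,
    center_crop_pair,
    normalize_pair,
    replicate_channels,
    sample_patch,
)
from srcorrect.errors import ConfigurationError, ShapeError
from srcorrect.nn import AdamW, EMA
from srcorrect.sdresnet import SDResNet

LOSS_VARIANTS = ("absolute", "squared")


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 2000
    warmup_epochs: int = 5
    base_lr: float = 2e-4
    weight_decay: float = 1e-2
    ema_decay: float = 0.992
    patience: int = 20
    checkpoint_gate_epoch: int = 21
    batch_size: int = 8
    seed: int = 0
    loss_variant: str = "absolute"
    patch: int | None = None
    norm_scope: str = "patch"
    improvement_rtol: float = 1e-4

    def __post_init__(self) -> None:
        if self.warmup_epochs >= self.max_epochs:
            raise ConfigurationError("warm-up must be shorter than the training run")
        if not 0 < self.ema_decay < 1:
            raise ConfigurationError("EMA decay must be in (0, 1)")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.loss_variant not in LOSS_VARIANTS:
            raise ConfigurationError(f"loss variant must be one of {LOSS_VARIANTS}")
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")
        if self.norm_scope not in ("patch", "image"):
            raise ConfigurationError("norm_scope must be 'patch' or 'image'")


@dataclass
class CheckpointState:
    best_val_loss: float = math.inf
    best_epoch: int | None = None
    best_raw_weights: dict | None = None
    best_ema_weights: dict | None = None
    last_weights: dict | None = None
    last_ema_weights: dict | None = None


def loss_fn(pred: np.ndarray, gt: np.ndarray, variant: str = "absolute") -> float:
    """Mean over all pixels of |pred−gt| (absolute) or (pred−gt)² (squared)."""
    if pred.shape != gt.shape:
        raise ShapeError(f"prediction {pred.shape} vs target {gt.shape}")
    if variant not in LOSS_VARIANTS:
        raise ConfigurationError(f"loss variant must be one of {LOSS_VARIANTS}")
    diff = pred - gt
    return float(np.mean(np.abs(diff)) if variant == "absolute" else np.mean(diff ** 2))


def loss_grad(pred: np.ndarray, gt: np.ndarray, variant: str = "absolute"):
    """Loss value and its gradient with respect to ``pred``."""
    if pred.shape != gt.shape:
        raise ShapeError(f"prediction {pred.shape} vs target {gt.shape}")
    diff = pred - gt
    n = diff.size
    if variant == "absolute":
        return float(np.mean(np.abs(diff))), np.sign(diff) / n
    return float(np.mean(diff ** 2)), 2.0 * diff / n


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate for a 0-based epoch index: linear warm-up then cosine decay."""
    if not 0 <= epoch < config.max_epochs:
        raise ConfigurationError("epoch outside the configured range")
    if epoch < config.warmup_epochs:
        return config.base_lr * (epoch + 1) / config.warmup_epochs
    span = config.max_epochs - config.warmup_epochs
    return config.base_lr * 0.5 * (1.0 + math.cos(math.pi * (epoch - config.warmup_epochs) / span))


def ema_update(ema_weights: dict, weights: dict, decay: float) -> dict:
    """Per-parameter EMA step: ema <- decay*ema + (1-decay)*w."""
    if set(ema_weights) != set(weights):
        raise ConfigurationError("parameter sets do not match")
    return {k: decay * ema_weights[k] + (1.0 - decay) * weights[k] for k in weights}


def _prepare_pair(pair: TrainingPair, patch: int | None, rng, augment: bool,
                  norm_scope: str = "patch"):
    """Optional patch sampling + flips, pairwise normalization, channel
    replication.  With ``norm_scope='patch'`` the GT-percentile interval is
    computed on the sampled patch; with ``'image'`` on the full image."""
    if norm_scope == "image":
        pair, _ = normalize_pair(pair)
    if patch is not None:
        if augment:
            pair = sample_patch(pair, patch, rng)
        else:
            pair = center_crop_pair(pair, patch)
    if norm_scope == "patch":
        pair, _ = normalize_pair(pair)
    if augment:
        pair = augment_flip(pair, rng)
    x = replicate_channels(pair.degraded)
    y = pair.gt[None, :, :]
    return x.astype(np.float32), y.astype(np.float32)


def _epoch_batches(pairs, patch, batch_size, rng, augment, norm_scope="patch"):
    order = rng.permutation(len(pairs)) if augment else np.arange(len(pairs))
    for start in range(0, len(order), batch_size):
        chunk = order[start:start + batch_size]
        xs, ys = zip(*(_prepare_pair(pairs[i], patch, rng, augment, norm_scope)
                       for i in chunk))
        yield np.stack(xs), np.stack(ys)


def train(model: SDResNet, train_set: list[TrainingPair], val_set: list[TrainingPair],
          config: TrainConfig, log_path=None):
    """Optimize the model; returns (CheckpointState, history).

    ``history`` has one row per epoch: epoch (1-based), lr, train_loss and
    the EMA-weight validation loss.
    """
    if not train_set or not val_set:
        raise ConfigurationError("training and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    model.freeze_encoder_bn()
    opt = AdamW(model.parameters(), lr=config.base_lr, weight_decay=config.weight_decay)
    ema = EMA(model, config.ema_decay)
    state = CheckpointState()
    history: list[dict] = []
    bad_epochs = 0

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_schedule(epoch - 1, config)
        opt.lr = lr
        losses = []
        for xb, yb in _epoch_batches(train_set, config.patch, config.batch_size, rng, True,
                                     config.norm_scope):
            pred = model.forward(xb, train=True)
            loss, dpred = loss_grad(pred, yb, config.loss_variant)
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dpred.astype(np.float32))
            opt.step()
            ema.update()
            losses.append(loss)
        train_loss = float(np.mean(losses))

        with ema.swapped_in():
            val_losses = [
                loss_fn(model.forward(xb, train=False), yb, config.loss_variant)
                for xb, yb in _epoch_batches(val_set, config.patch, config.batch_size, rng, False,
                             config.norm_scope)
            ]
        val_loss = float(np.mean(val_losses))
        if not math.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append({"epoch": epoch, "lr": lr, "train_loss": train_loss,
                        "val_loss_ema": val_loss})

        if not math.isfinite(state.best_val_loss):
            improved = True
        elif state.best_val_loss <= 0:
            improved = val_loss < state.best_val_loss
        else:
            improved = (state.best_val_loss - val_loss) / state.best_val_loss > config.improvement_rtol
        if improved:
            bad_epochs = 0
            state.best_val_loss = val_loss
            if epoch > config.checkpoint_gate_epoch:
                state.best_epoch = epoch
                state.best_raw_weights = model.state_dict()
                state.best_ema_weights = ema.state()
        else:
            bad_epochs += 1
        if bad_epochs > config.patience:
            break

    state.last_weights = model.state_dict()
    state.last_ema_weights = ema.state()
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "lr", "train_loss", "val_loss_ema"])
            writer.writeheader()
            writer.writerows(history)
    return state, history


def inference_weights(state: CheckpointState) -> dict:
    """EMA weights of the best gated checkpoint, falling back to the last epoch."""
    for cand in (state.best_ema_weights, state.last_ema_weights, state.best_raw_weights,
                 state.last_weights):
        if cand is not None:
            return cand
    raise ConfigurationError("checkpoint state holds no weights")
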