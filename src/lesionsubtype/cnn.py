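"""VGG-style 3D CNN for severe-aphasia classification.

The network consumes one scaled ordinal morphometry map per subject and
outputs class probabilities.  Architecture: 4-5 blocks of shape-preserving
3x3x3 convolutions + ReLU, each block closed by a 2x ceil-mode max pool,
followed by three fully connected layers -- FC1 at twice the last
convolutional channel count (with batch normalization and dropout), FC2 at
the last-conv channel count (the latent layer exposed to downstream SVMs),
and FC3 at the number of classes.

Training minimizes cross entropy weighted by inverse class frequencies under
plain SGD with a cosine-annealing warm-restart schedule (initial period 50
epochs, doubling at each restart, floor 1e-10), early stopping on validation
loss with best-weight restore, and L2 decay on weights only.

Four complexity presets span the tuned range: block counts 4-5, convolutions
per block 1-4, channels 8-128.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import (ArchitectureError, ArgumentError, DegenerateLabelError,
                     DivergenceError, TuningError)
from .partitions import CVPlan, split_train_validation

log = logging.getLogger(__name__)

#: Complexity presets: (convs per block, channels per block).
COMPLEXITY_PRESETS: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {
    1: ((1, 1, 1, 1), (8, 16, 32, 64)),
    2: ((2, 2, 2, 2), (16, 32, 64, 128)),
    3: ((2, 2, 2, 2, 2), (8, 16, 32, 64, 128)),
    4: ((2, 2, 3, 3, 4), (8, 16, 32, 64, 128)),
}

DROPOUT_GRID = (0.6, 0.7, 0.8)
L2_GRID = (0.001, 0.01)
RATE_GRID = (0.1e-4, 0.8e-4, 1e-4)


@dataclass(frozen=True)
class CNNConfig:
    complexity_level: int = 1
    dropout_rate: float = 0.6
    l2_penalty: float = 0.001
    base_learning_rate: float = 1e-4
    n_classes: int = 2
    input_shape: tuple[int, int, int] = (12, 14, 12)

    def __post_init__(self):
        if self.complexity_level not in COMPLEXITY_PRESETS:
            raise ArgumentError(
                f"complexity_level must be in {sorted(COMPLEXITY_PRESETS)}")
        convs, channels = COMPLEXITY_PRESETS[self.complexity_level]
        if not 4 <= len(channels) <= 5:
            raise ArchitectureError("blocks must number 4-5")
        if any(not 8 <= c <= 128 for c in channels):
            raise ArchitectureError("channels per layer must be within [8,128]")
        if any(not 1 <= k <= 4 for k in convs):
            raise ArchitectureError("convolutions per block must be within [1,4]")

    @property
    def blocks(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return COMPLEXITY_PRESETS[self.complexity_level]

    @property
    def latent_width(self) -> int:
        return self.blocks[1][-1]


@dataclass(frozen=True)
class TrainingSchedule:
    total_epochs: int = 800
    batch_size: int = 128
    restart_period_0: int = 50
    period_multiplier: int = 2
    floor_rate: float = 1e-10
    early_stop_patience: int = 100
    min_delta: float = 1e-4


def class_weights(labels) -> np.ndarray:
    """Inverse class-frequency weights, indexed by class label."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise DegenerateLabelError("both classes must be present")
    n = labels.size
    w = np.zeros(int(classes.max()) + 1)
    for c in classes:
        w[int(c)] = n / np.sum(labels == c)
    return w


def cosine_warm_restart_rate(
    epoch: int, schedule: TrainingSchedule, base_rate: float
) -> float:
    """Learning rate under cosine annealing with warm restarts.

    Cycle i spans ``restart_period_0 * multiplier**i`` epochs (restarts at
    cumulative epochs 50, 150, 350, 750 under the defaults); within a cycle of
    length T the rate decays from ``base_rate`` at the first epoch to the
    floor at the last: ``floor + 0.5*(base-floor)*(1 + cos(pi*t/(T-1)))``.
    """
    if epoch < 0:
        raise ArgumentError("epoch must be nonnegative")
    start, period = 0, schedule.restart_period_0
    while epoch >= start + period:
        start += period
        period *= schedule.period_multiplier
    t = epoch - start
    span = max(period - 1, 1)
    cos_term = 0.5 * (1.0 + np.cos(np.pi * min(t, span) / span))
    return schedule.floor_rate + (base_rate - schedule.floor_rate) * cos_term


def restart_epochs(schedule: TrainingSchedule) -> list[int]:
    """Cumulative epochs at which the schedule restarts, within total_epochs."""
    out, start, period = [], 0, schedule.restart_period_0
    while start + period < schedule.total_epochs:
        start += period
        out.append(start)
        period *= schedule.period_multiplier
    return out


def build_cnn(config: CNNConfig, seed: int = 0) -> nn.Sequential:
    """Assemble the untrained network for ``config``."""
    convs, channels = config.blocks
    nn.spatial_after_pools(config.input_shape, len(channels))  # validates
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7])
    layers: list[nn.Layer] = []
    cin = 1
    for n_conv, cout in zip(convs, channels):
        for _ in range(n_conv):
            layers.append(nn.Conv3d(cin, cout, rng))
            layers.append(nn.ReLU())
            cin = cout
        layers.append(nn.MaxPool3d())
    final_spatial = nn.spatial_after_pools(config.input_shape, len(channels))[-1]
    flat = channels[-1] * int(np.prod(final_spatial))
    layers.append(nn.Flatten())
    layers.append(nn.Linear(flat, 2 * channels[-1], rng))
    layers.append(nn.BatchNorm1d(2 * channels[-1]))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(config.dropout_rate))
    layers.append(nn.Linear(2 * channels[-1], channels[-1], rng))
    layers.append(nn.ReLU())
    layers.append(nn.Linear(channels[-1], config.n_classes, rng))
    model = nn.Sequential(layers)
    model.config = config
    # index of the last convolution's ReLU output (for Grad-CAM++)
    conv_relu_indices = [i for i, l in enumerate(layers)
                         if isinstance(l, nn.ReLU)
                         and i >= 1 and isinstance(layers[i - 1], nn.Conv3d)]
    model.last_conv_index = conv_relu_indices[-1]
    # index of the FC2 ReLU output (the latent layer)
    model.latent_index = len(layers) - 2
    return model


@dataclass
class TrainedCNN:
    model: nn.Sequential
    config: CNNConfig
    training_log: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_validation_loss: float = np.inf

    @property
    def latent_width(self) -> int:
        return self.config.latent_width


def _as_batch(X: np.ndarray) -> np.ndarray:
    return X[:, None, ...].astype(nn.DTYPE)  # add channel axis


def train_cnn(
    model: nn.Sequential,
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    schedule: TrainingSchedule,
    seed: int = 0,
    base_rate: float | None = None,
    l2_penalty: float | None = None,
) -> TrainedCNN:
    """Train with early stopping on validation loss; restores best weights."""
    config: CNNConfig = model.config
    base_rate = config.base_learning_rate if base_rate is None else base_rate
    l2 = config.l2_penalty if l2_penalty is None else l2_penalty
    w = class_weights(y_train)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 13])
    Xtr, Xva = _as_batch(X_train), _as_batch(X_val)
    ytr = np.asarray(y_train, dtype=np.int64)
    yva = np.asarray(y_val, dtype=np.int64)

    trained = TrainedCNN(model=model, config=config)
    best_state = model.state()
    stale = 0
    for epoch in range(schedule.total_epochs):
        lr = cosine_warm_restart_rate(epoch, schedule, base_rate)
        perm = rng.permutation(len(ytr))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(ytr), schedule.batch_size):
            sel = perm[start:start + schedule.batch_size]
            model.zero_grad()
            logits = model.forward(Xtr[sel], training=True, rng=rng)
            loss, grad = nn.weighted_cross_entropy(logits, ytr[sel], w)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            model.backward(grad)
            nn.sgd_step(model, lr, weight_decay=l2)
            epoch_loss += loss
            n_batches += 1
        val_logits = model.forward(Xva, training=False)
        val_loss, _ = nn.weighted_cross_entropy(val_logits, yva, class_weights_or(w, yva))
        if not np.isfinite(val_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        trained.training_log.append({
            "epoch": epoch, "lr": lr,
            "train_loss": epoch_loss / max(n_batches, 1),
            "validation_loss": val_loss,
        })
        if val_loss < trained.best_validation_loss - schedule.min_delta:
            trained.best_validation_loss = val_loss
            trained.best_epoch = epoch
            best_state = model.state()
            stale = 0
        else:
            stale += 1
            if stale >= schedule.early_stop_patience:
                break
    model.load_state(best_state)
    return trained


def class_weights_or(train_weights: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Training-set class weights, padded if validation lacks a class."""
    if int(labels.max()) < len(train_weights):
        return train_weights
    out = np.ones(int(labels.max()) + 1)
    out[:len(train_weights)] = train_weights
    return out


def predict_and_latent(
    trained: TrainedCNN, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and FC2 (latent) activations, eval mode."""
    model = trained.model
    logits = model.forward(_as_batch(X), training=False)
    latent = model.activation(model.latent_index)
    return nn.softmax(logits), latent.copy()


def evaluate_loss(trained: TrainedCNN, X, y) -> float:
    w = class_weights_or(class_weights(y) if len(np.unique(y)) > 1
                         else np.ones(2), np.asarray(y))
    logits = trained.model.forward(_as_batch(X), training=False)
    loss, _ = nn.weighted_cross_entropy(logits, np.asarray(y, dtype=np.int64), w)
    return loss


def default_config_grid(input_shape) -> list[CNNConfig]:
    """Full tuning grid: complexity x dropout x L2 x learning rate."""
    return [
        CNNConfig(complexity_level=c, dropout_rate=d, l2_penalty=l,
                  base_learning_rate=r, input_shape=tuple(input_shape))
        for c in COMPLEXITY_PRESETS for d in DROPOUT_GRID
        for l in L2_GRID for r in RATE_GRID
    ]


def tune_and_refit(
    X: np.ndarray, y: np.ndarray,
    plan: CVPlan, repeat: int, fold: int,
    config_grid: list[CNNConfig],
    schedule: TrainingSchedule,
    seed: int = 0,
) -> tuple[TrainedCNN, CNNConfig, list[dict]]:
    """Grid search on the inner folds, then refit on the whole outer train.

    Selection minimizes the mean inner-fold validation loss (not accuracy).
    The winner is refit on the outer-train set with the plan's stratified
    70/30 train/validation split to drive early stopping.
    """
    if not config_grid:
        raise TuningError("empty configuration grid")
    outer_train = plan.outer_train(repeat, fold)
    inner = plan.inner[repeat][fold]
    records = []
    for ci, config in enumerate(config_grid):
        losses = []
        inner_proba = []
        try:
            for gi, val_idx in enumerate(inner):
                val_set = set(val_idx.tolist())
                tr_idx = np.array([i for i in outer_train if i not in val_set])
                model = build_cnn(config, seed=seed + 1000 * ci + gi)
                trained = train_cnn(model, X[tr_idx], y[tr_idx],
                                    X[val_idx], y[val_idx], schedule,
                                    seed=seed + 1000 * ci + gi)
                losses.append(evaluate_loss(trained, X[val_idx], y[val_idx]))
                proba, _ = predict_and_latent(trained, X[val_idx])
                inner_proba.append((val_idx, proba))
        except DivergenceError as exc:
            records.append({"config": config, "mean_inner_loss": np.inf,
                            "criterion": "mean_inner_loss", "error": str(exc)})
            continue
        records.append({"config": config,
                        "mean_inner_loss": float(np.mean(losses)),
                        "criterion": "mean_inner_loss",
                        "inner_proba": inner_proba})
    finite = [r for r in records if np.isfinite(r["mean_inner_loss"])]
    if not finite:
        raise TuningError(f"all candidates diverged: {records}")
    best = min(finite, key=lambda r: r["mean_inner_loss"])
    config = best["config"]

    tr, va = split_train_validation(outer_train, plan.strata, 0.3,
                                    seed=seed + repeat * 17 + fold)
    model = build_cnn(config, seed=seed)
    trained = train_cnn(model, X[tr], y[tr], X[va], y[va], schedule, seed=seed)
    return trained, config, records
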