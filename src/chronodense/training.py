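"""Optimisation recipe: smoothed losses, warm-restart schedule, Adam fit loop.

The loss is the head-appropriate cross entropy with label smoothing, plus an
explicit L2 penalty ``weight_l2 * sum ||w||^2`` over *all* parameters.
Gradients are clipped by global norm each step, the learning rate follows
cosine annealing with warm restarts at epoch granularity, and every source of
randomness (shuffling) is derived from ``TrainConfig.seed``, so two runs with
the same seed produce bit-identical histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import log_softmax, expit

from .model import Network

__all__ = [
    "TrainConfig",
    "smoothed_cross_entropy",
    "binary_loss",
    "warm_restart_lr",
    "fit",
    "FitResult",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters.

    ``restart_period`` (epochs) and ``restart_mult`` define the warm-restart
    cycles: cycle ``j`` lasts ``restart_period * restart_mult**j`` epochs and
    the learning rate anneals from ``learning_rate`` down to ``eta_min``
    within each cycle, snapping back to ``learning_rate`` at every restart.
    """

    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 100
    weight_l2: float = 0.01
    clip_max_norm: float = 1.0
    label_smoothing: float = 0.1
    restart_period: int = 10
    restart_mult: int = 2
    eta_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        if self.eta_min > self.learning_rate:
            raise ValueError("eta_min must not exceed learning_rate")
        if self.weight_l2 < 0 or self.clip_max_norm <= 0:
            raise ValueError("weight_l2 must be >= 0 and clip_max_norm > 0")
        if min(self.batch_size, self.epochs, self.restart_period, self.restart_mult) < 1:
            raise ValueError("batch_size, epochs, restart_period, restart_mult must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


# -- losses ------------------------------------------------------------------


def smoothed_cross_entropy(scores: np.ndarray, labels: np.ndarray, eps: float = 0.0) -> float:
    """Categorical cross entropy with label smoothing.

    ``(1 - eps) * CE(scores, labels) + eps * CE(scores, uniform)``, averaged
    over the batch; at ``eps = 0`` this is the plain cross entropy.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("scores must be [N, K] with K >= 2")
    n, k = scores.shape
    if labels.shape != (n,):
        raise ValueError(f"labels must be shape ({n},)")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    logp = log_softmax(scores, axis=1)
    ce = -logp[np.arange(n), labels].mean()
    ce_uniform = -logp.mean()  # mean over batch of (1/K) sum_k log p_k
    return float((1.0 - eps) * ce + eps * ce_uniform)


def _smoothed_ce_grad(scores: np.ndarray, labels: np.ndarray, eps: float) -> np.ndarray:
    n, k = scores.shape
    p = np.exp(log_softmax(scores, axis=1))
    target = np.full((n, k), eps / k)
    target[np.arange(n), labels] += 1.0 - eps
    return (p - target) / n


def binary_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 0.0) -> float:
    """Mean element-wise binary cross entropy on sigmoid scores.

    With smoothing ``eps > 0`` the 0/1 targets are relaxed to ``eps/2`` and
    ``1 - eps/2``.  ``scores`` may be ``[N]`` or ``[N, L]`` (multi-label).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"scores shape {scores.shape} != labels shape {labels.shape}")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    y = labels * (1.0 - eps) + eps / 2.0
    # numerically stable BCE-with-logits
    loss = np.maximum(scores, 0.0) - scores * y + np.log1p(np.exp(-np.abs(scores)))
    return float(loss.mean())


def _binary_loss_grad(scores: np.ndarray, labels: np.ndarray, eps: float) -> np.ndarray:
    y = labels * (1.0 - eps) + eps / 2.0
    return (expit(scores) - y) / scores.size


# -- learning-rate schedule --------------------------------------------------


def warm_restart_lr(epoch_fraction: float, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate with warm restarts.

    Within cycle ``j`` of length ``T_j = restart_period * restart_mult**j``:
    ``lr(t) = eta_min + (lr_max - eta_min) * (1 + cos(pi * t / T_j)) / 2``
    where ``t`` is the (fractional) epoch count since the last restart, so
    the rate is exactly ``lr_max`` at every restart boundary.
    """
    if epoch_fraction < 0:
        raise ValueError("epoch_fraction must be >= 0")
    t = float(epoch_fraction)
    period = float(cfg.restart_period)
    while t >= period:
        t -= period
        period *= cfg.restart_mult
    cosine = (1.0 + math.cos(math.pi * t / period)) / 2.0
    return cfg.eta_min + (cfg.learning_rate - cfg.eta_min) * cosine


# -- fit loop ----------------------------------------------------------------


@dataclass
class FitResult:
    """Per-epoch history plus the best-validation parameter snapshot."""

    history: list[dict]
    best_state: list[np.ndarray]
    best_epoch: int
    best_valid_acc: float

    def history_array(self) -> np.ndarray:
        cols = ("epoch", "lr", "train_loss", "train_acc", "valid_loss", "valid_acc")
        return np.array([[row[c] for c in cols] for row in self.history])


def _loss_and_grad(model: Network, scores: np.ndarray, y: np.ndarray, eps: float):
    if model.config.head == "multiclass-softmax":
        return (
            smoothed_cross_entropy(scores, y, eps),
            _smoothed_ce_grad(scores, y.astype(int), eps),
        )
    yb = np.asarray(y, dtype=float)
    if yb.ndim == 1:
        yb = yb[:, None]
    return binary_loss(scores, yb, eps), _binary_loss_grad(scores, yb, eps)


def _accuracy(model: Network, scores: np.ndarray, y: np.ndarray) -> float:
    if model.config.head == "multiclass-softmax":
        return float((scores.argmax(axis=1) == y).mean())
    yb = np.asarray(y, dtype=float)
    if yb.ndim == 1:
        yb = yb[:, None]
    return float(((scores > 0) == (yb > 0.5)).mean())


def _evaluate(model: Network, x: np.ndarray, y: np.ndarray, eps: float,
              batch_size: int) -> tuple[float, float]:
    scores = model.predict_scores(x, batch_size=batch_size)
    loss, _ = _loss_and_grad(model, scores, y, eps)
    return loss, _accuracy(model, scores, y)


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so the global L2 norm is <= ``max_norm``."""
    total = math.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


def fit(
    model: Network,
    train_data: tuple[np.ndarray, np.ndarray],
    valid_data: tuple[np.ndarray, np.ndarray] | None,
    cfg: TrainConfig,
) -> FitResult:
    """Train with Adam, global-norm clipping, L2 penalty and warm restarts.

    ``train_data``/``valid_data`` are ``(X [N, C, T], y)`` pairs matching the
    model head.  Raises on an empty dataset and fails loudly (with the epoch
    index) if the loss goes non-finite.
    """
    x_train, y_train = train_data
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train)
    if len(x_train) == 0:
        raise ValueError("training dataset is empty")
    if valid_data is not None and len(valid_data[0]) == 0:
        raise ValueError("validation dataset is empty")

    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    eps = cfg.label_smoothing

    history: list[dict] = []
    best_state = model.get_state()
    best_epoch, best_acc = -1, -math.inf

    for epoch in range(cfg.epochs):
        lr = warm_restart_lr(epoch, cfg)
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct_w = 0.0, 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            scores = model.forward(xb)
            data_loss, gscores = _loss_and_grad(model, scores, yb, eps)
            model.backward(gscores)
            grads = model.gradients()
            l2 = 0.0
            for p, g in zip(params, grads):
                l2 += float((p * p).sum())
                g += 2.0 * cfg.weight_l2 * p
            loss = data_loss + cfg.weight_l2 * l2
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            clip_global_norm(grads, cfg.clip_max_norm)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1.0 - beta1) * g
                vi *= beta2
                vi += (1.0 - beta2) * g * g
                p -= lr * (mi / bc1) / (np.sqrt(vi / bc2) + adam_eps)
            epoch_loss += loss * len(idx)
            epoch_correct_w += _accuracy(model, scores, yb) * len(idx)

        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": epoch_loss / len(order),
            "train_acc": epoch_correct_w / len(order),
            "valid_loss": math.nan,
            "valid_acc": math.nan,
        }
        if valid_data is not None:
            vloss, vacc = _evaluate(model, valid_data[0], valid_data[1], eps, cfg.batch_size)
            row["valid_loss"], row["valid_acc"] = vloss, vacc
            if vacc > best_acc:
                best_acc, best_epoch = vacc, epoch
                best_state = model.get_state()
        history.append(row)

    if valid_data is None:
        best_state, best_epoch, best_acc = model.get_state(), cfg.epochs - 1, math.nan
    return FitResult(history, best_state, best_epoch, float(best_acc))
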