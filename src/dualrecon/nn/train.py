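"""Mini-batch training loop: MSE loss, RMSProp, LR plateau schedule, early stop."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .unet import UNet

__all__ = ["RMSProp", "EpochRecord", "TrainHistory", "train_network"]


class RMSProp:
    """RMSProp: ``cache = rho*cache + (1-rho)*g^2; w -= lr*g/(sqrt(cache)+eps)``."""

    def __init__(self, params, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for (p, g), c in zip(self.params, self.cache):
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(c) + self.eps)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    lr: float


@dataclass
class TrainHistory:
    """Per-epoch losses and learning rates of one training stage."""

    epochs: list[EpochRecord] = field(default_factory=list)
    initial_val_loss: float = float("nan")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def val_losses(self) -> list[float]:
        return [e.val_loss for e in self.epochs]

    @property
    def lrs(self) -> list[float]:
        return [e.lr for e in self.epochs]

    def best_val_loss(self) -> float:
        return min(self.val_losses) if self.epochs else float("nan")

    def to_rows(self) -> list[dict]:
        return [vars(e) for e in self.epochs]


def _batch_loss(net: UNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, 0
    for lo in range(0, x.shape[0], batch_size):
        xb, yb = x[lo:lo + batch_size], y[lo:lo + batch_size]
        pred = net.forward(xb, training=False)
        total += float(np.sum((pred - yb) ** 2))
        n += yb.size
    return total / n


def train_network(
    net: UNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    lr0: float = 1e-3,
    lr_factor: float = 0.1,
    lr_patience: int = 10,
    early_patience: int = 20,
    batch_size: int = 8,
    max_epochs: int = 30,
    seed: int = 0,
    restore_best: bool = True,
    calibrate_head: bool = True,
) -> TrainHistory:
    """Train ``net`` in place on channel-packed float arrays.

    The learning rate is cut by ``lr_factor`` after ``lr_patience``
    consecutive epochs without validation improvement; training stops early
    after ``early_patience`` epochs without improvement.  With
    ``restore_best`` the full state (weights and BN statistics) of the best
    validation epoch is kept.

    ``calibrate_head`` initializes the affine parameters of the final batch
    normalization to the per-channel mean/std of the training labels, so the
    standardized head output starts on the label scale instead of having to
    crawl there; it is equivalent to training against standardized targets.
    """
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32)
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("empty training or validation set")

    if calibrate_head and hasattr(net, "head_bn"):
        net.head_bn.gamma[...] = y_train.std(axis=(0, 2, 3)) + 1e-8
        net.head_bn.beta[...] = y_train.mean(axis=(0, 2, 3))

    rng = np.random.default_rng(seed)
    opt = RMSProp(net.params(), lr=lr0)
    history = TrainHistory()
    history.initial_val_loss = _batch_loss(net, x_val, y_val, batch_size)

    best_val = np.inf
    best_weights = net.get_weights() if restore_best else None
    stale = 0        # epochs since improvement, for the LR schedule
    stale_total = 0  # epochs since improvement, for early stopping
    n = x_train.shape[0]

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        run_loss, run_n = 0.0, 0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            pred = net.forward(xb, training=True)
            diff = pred - yb
            run_loss += float(np.sum(diff ** 2))
            run_n += yb.size
            net.backward((2.0 / diff.size) * diff)
            opt.step()
        val_loss = _batch_loss(net, x_val, y_val, batch_size)
        history.epochs.append(EpochRecord(epoch, run_loss / run_n, val_loss, opt.lr))

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            stale = stale_total = 0
            if restore_best:
                best_weights = net.get_weights()
        else:
            stale += 1
            stale_total += 1
            if stale >= lr_patience:
                opt.lr *= lr_factor
                stale = 0
            if stale_total >= early_patience:
                break

    if restore_best and best_weights is not None:
        net.set_weights(best_weights)
    return history
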