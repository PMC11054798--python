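"""Network training: ADAM with per-epoch learning-rate decay, periodic
validation, and best-checkpoint early stopping.

Defaults follow the estimator's training protocol: initial learning rate
0.0012, batch size 128, learning rate multiplied by 0.2 after every epoch,
training data reshuffled each epoch, validation loss computed every 800
iterations, and training stopped once the validation loss has failed to
improve on the best value for 2 consecutive evaluations. The parameters
from the best validation evaluation are returned.

Inputs are standardized per channel with training-set statistics (stored in
the checkpoint); windows whose phase label is invalid (standing) are
excluded from both training and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import Network
from .nn import Adam
from .windowing import WindowSet

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Standardizer",
    "masked_mse_loss",
    "train_network",
]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.0012
    batch_size: int = 128
    lr_decay_factor: float = 0.2  # applied once per epoch
    val_every: int = 800  # iterations between validation evaluations
    early_stop_patience: int = 2  # consecutive non-improving evaluations
    max_epochs: int = 10
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.lr0 <= 0 or self.batch_size < 1 or self.early_stop_patience < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)  # per iteration
    val_loss: list[float] = field(default_factory=list)  # per evaluation
    val_iteration: list[int] = field(default_factory=list)
    best_val_loss: float = np.inf
    best_iteration: int = -1
    final_lr: float = 0.0
    stopped_early: bool = False
    epochs_run: int = 0


@dataclass
class Standardizer:
    """Per-channel affine normalization fit on the training windows."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, *arrays: np.ndarray) -> "Standardizer":
        flat = np.concatenate([a.reshape(-1, a.shape[-1]) for a in arrays])
        std = flat.std(axis=0)
        std[std < 1e-9] = 1.0
        return cls(mean=flat.mean(axis=0), std=std)

    @classmethod
    def identity(cls, n_channels: int) -> "Standardizer":
        return cls(mean=np.zeros(n_channels), std=np.ones(n_channels))

    def apply(self, a: np.ndarray) -> np.ndarray:
        return (a - self.mean) / self.std


def masked_mse_loss(
    pred: np.ndarray,
    target: np.ndarray,
    valid: np.ndarray | None = None,
    *,
    return_grad: bool = False,
):
    """Mean squared error over valid samples and all 4 output components.

    Optionally also returns the gradient with respect to ``pred`` (zero on
    masked samples), normalized so the loss is the mean over
    ``n_valid * 4`` squared differences.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    if valid is None:
        valid = np.ones(pred.shape[0], dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("all samples are masked; loss undefined")
    diff = (pred - target) * valid[:, None]
    denom = n * pred.shape[1]
    loss = float(np.sum(diff**2) / denom)
    if return_grad:
        return loss, 2.0 * diff / denom
    return loss


def _evaluate(net: Network, std: Standardizer, ws: WindowSet,
              batch: int = 512) -> float:
    losses = []
    counts = []
    for i in range(0, len(ws), batch):
        sl = slice(i, i + batch)
        pred = net.forward(
            std.apply(ws.long[sl]),
            None if net.head_short is None else std.apply(ws.short[sl]),
            train=False,
        )
        losses.append(masked_mse_loss(pred, ws.target[sl]))
        counts.append(ws.target[sl].shape[0])
    return float(np.average(losses, weights=counts))


def train_network(
    net: Network,
    train_windows: WindowSet,
    val_windows: WindowSet,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[Network, TrainHistory, Standardizer]:
    """Train ``net`` in place and restore the best-validation parameters.

    Windows with invalid targets are dropped from both sets. The learning
    rate for epoch ``e`` is ``lr0 * lr_decay_factor**e`` exactly. Training
    stops after ``early_stop_patience`` consecutive validation evaluations
    without improvement over the best loss so far, or after ``max_epochs``.
    """
    train_windows = train_windows.valid_only()
    val_windows = val_windows.valid_only()
    if len(train_windows) == 0 or len(val_windows) == 0:
        raise ValueError("training and validation sets must be nonempty")

    std = (Standardizer.fit(train_windows.long, train_windows.short)
           if cfg.standardize
           else Standardizer.identity(train_windows.long.shape[-1]))

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), lr=cfg.lr0)
    hist = TrainHistory()
    best_state = net.state_dict()
    n = len(train_windows)
    dual = net.head_short is not None

    iteration = 0
    bad_evals = 0
    stop = False
    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr0 * cfg.lr_decay_factor**epoch
        hist.final_lr = opt.lr
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xl = std.apply(train_windows.long[idx])
            xs = std.apply(train_windows.short[idx]) if dual else None
            pred = net.forward(xl, xs, train=True)
            loss, grad = masked_mse_loss(pred, train_windows.target[idx],
                                         return_grad=True)
            grad = grad.astype(pred.dtype, copy=False)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at iteration {iteration}")
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            hist.train_loss.append(loss)
            iteration += 1

            if iteration % cfg.val_every == 0:
                vloss = _evaluate(net, std, val_windows)
                hist.val_loss.append(vloss)
                hist.val_iteration.append(iteration)
                if vloss < hist.best_val_loss:
                    hist.best_val_loss = vloss
                    hist.best_iteration = iteration
                    best_state = net.state_dict()
                    bad_evals = 0
                else:
                    bad_evals += 1
                    if bad_evals >= cfg.early_stop_patience:
                        hist.stopped_early = True
                        stop = True
                        break
        hist.epochs_run = epoch + 1
        if stop:
            break

    # final evaluation if none landed on the last iteration
    if not stop and (not hist.val_iteration or hist.val_iteration[-1] != iteration):
        vloss = _evaluate(net, std, val_windows)
        hist.val_loss.append(vloss)
        hist.val_iteration.append(iteration)
        if vloss < hist.best_val_loss:
            hist.best_val_loss = vloss
            hist.best_iteration = iteration
            best_state = net.state_dict()

    net.load_state_dict(best_state)
    return net, hist, std
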