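"""Losses, augmentation and the training loops.

Two tasks share one loop:

``segmentation``
    Soft Dice loss on sigmoid probabilities against Boolean targets,
    Adam at learning rate 1e-4, random per-axis flips.
``restoration``
    Noise2Clean regression: mean squared error between the head-less
    network output on a noisy tile and the aligned clean tile, Adam at
    learning rate 1e-5.

The loop uses a constant learning rate (no scheduler), full shuffling
without replacement each epoch, and is bit-reproducible given the seed.
Loss is always computed on soft probabilities; thresholding happens only
at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, BatchNorm3d
from .model import VoxResNet

__all__ = [
    "TrainConfig",
    "LossCurve",
    "dice_loss",
    "mse_loss",
    "random_flip",
    "iterations_per_epoch",
    "train",
]

#: smoothing constant in the soft-Dice numerator and denominator; keeps
#: all-background tiles (sum pred = sum truth = 0) at loss 0 instead of 0/0
DICE_SMOOTH = 1e-6

_TASKS = ("segmentation", "restoration")
_DEFAULT_LR = {"segmentation": 1e-4, "restoration": 1e-5}
_DEFAULT_EPOCHS = {"segmentation": 1500, "restoration": 500}


@dataclass
class TrainConfig:
    """Optimisation hyperparameters; defaults follow the study protocol."""

    task: str = "segmentation"
    learning_rate: float | None = None
    batch_size: int = 64
    epochs: int | None = None
    flip_augment: bool | None = None
    seed: int = 0
    device: str = "cpu"
    #: Adam moment decays; beta2 below the 0.999 default adapts faster on
    #: short schedules
    adam_betas: tuple[float, float] = (0.9, 0.999)

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise ValueError(f"task must be one of {_TASKS}")
        if self.learning_rate is None:
            self.learning_rate = _DEFAULT_LR[self.task]
        if self.epochs is None:
            self.epochs = _DEFAULT_EPOCHS[self.task]
        if self.flip_augment is None:
            self.flip_augment = self.task == "segmentation"
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.device != "cpu":
            raise ValueError("only the cpu backend is available")


@dataclass
class LossCurve:
    """Per-epoch mean loss with the config that produced it."""

    losses: list[float]
    task: str
    config: TrainConfig

    def __len__(self) -> int:
        return len(self.losses)


# ---------------------------------------------------------------------------
# Losses (scalar forms + internal gradient forms)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_loss(pred: np.ndarray, truth: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """Soft Dice loss 1 - (2*sum(p*t)+s)/(sum(p)+sum(t)+s), in [0, 1]."""
    loss, _ = _dice_loss_grad(np.asarray(pred, dtype=np.float64),
                              np.asarray(truth, dtype=np.float64), smooth)
    return loss


def _dice_loss_grad(pred, truth, smooth=DICE_SMOOTH):
    _check_shapes(pred, truth)
    inter = float((pred * truth).sum())
    denom = float(pred.sum() + truth.sum()) + smooth
    loss = 1.0 - (2.0 * inter + smooth) / denom
    # d/dp_i of -(2*I+s)/(P+T+s) = -(2*t_i*denom - (2*I+s)) / denom^2
    grad = -(2.0 * truth * denom - (2.0 * inter + smooth)) / denom**2
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared voxel difference."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target)
    return float(np.mean((pred - target) ** 2))


def _mse_loss_grad(pred, target):
    _check_shapes(pred, target)
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


def random_flip(
    sample: tuple[np.ndarray, np.ndarray], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Independently flip each axis with probability 1/2, identically on
    the input and the target."""
    x, y = sample
    _check_shapes(np.asarray(x), np.asarray(y))
    axes = tuple(a for a in range(x.ndim) if rng.random() < 0.5)
    if not axes:
        return x, y
    return np.flip(x, axes).copy(), np.flip(y, axes).copy()


def iterations_per_epoch(n_samples: int, batch_size: int) -> int:
    """ceil(n_samples / batch_size); the final partial batch is included."""
    if n_samples < 1 or batch_size < 1:
        raise ValueError("n_samples and batch_size must be positive")
    return -(-n_samples // batch_size)


# ---------------------------------------------------------------------------
# Training loop


def _batch_loss_grad(task: str, prob: np.ndarray, target: np.ndarray):
    """Loss of one batch with its gradient w.r.t. prob.

    Soft Dice is computed jointly over the whole batch (one overlap ratio
    per optimisation step).  A per-sample mean would starve root-free
    tiles of gradient: with target identically zero the per-tile Dice
    gradient is O(smooth), so false positives in background tiles would
    never be penalised.  MSE is a plain mean either way.
    """
    if task == "segmentation":
        return _dice_loss_grad(prob, target)
    return _mse_loss_grad(prob, target)


def recalibrate_batchnorm(
    net: VoxResNet,
    inputs: list[np.ndarray],
    batch_size: int,
) -> None:
    """Re-estimate batch-norm running statistics over a dataset.

    Exponential running averages accumulated during a short training run
    lag the final weights, so evaluation-mode outputs drift from what the
    loss saw.  One extra pass with momentum 1/k replaces them with the
    plain average of the batch statistics under the trained weights.
    """
    bns = [m for m in net.walk() if isinstance(m, BatchNorm3d)]
    if not bns:
        return
    for bn in bns:
        bn.running_mean[...] = 0
        bn.running_var[...] = 0
    for k, start in enumerate(range(0, len(inputs), batch_size), start=1):
        for bn in bns:
            bn.momentum = 1.0 / k
        xb = np.stack(inputs[start : start + batch_size])[:, None]
        net.forward(xb.astype(np.float32), train=True)
    for bn in bns:
        bn.momentum = 0.1


def train(
    net: VoxResNet,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    log_every: int = 0,
) -> tuple[VoxResNet, LossCurve]:
    """Train the network in place and return it with its loss curve.

    ``dataset`` is a list of (input tile, target tile) pairs: Boolean
    targets for segmentation, unit-interval clean tiles for restoration.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    task = config.task
    if task == "segmentation":
        for _, t in dataset:
            if np.asarray(t).dtype != np.bool_:
                raise ValueError("segmentation targets must be Boolean")
    for x, t in dataset:
        _check_shapes(np.asarray(x), np.asarray(t))

    rng = np.random.default_rng(config.seed)
    opt = Adam(net.params(), lr=config.learning_rate, betas=config.adam_betas)
    n = len(dataset)
    curve: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, ts = [], []
            for i in idx:
                x, t = dataset[i]
                if config.flip_augment:
                    x, t = random_flip((np.asarray(x), np.asarray(t)), rng)
                xs.append(np.asarray(x, dtype=np.float32))
                ts.append(np.asarray(t, dtype=np.float32))
            xb = np.stack(xs)[:, None]
            tb = np.stack(ts)[:, None]
            prob = net.forward(xb, train=True)
            loss, grad = _batch_loss_grad(task, prob, tb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, batch "
                    f"{start // config.batch_size}"
                )
            opt.zero_grad()
            net.backward(grad.astype(prob.dtype))
            opt.step()
            epoch_losses.append(loss)
        curve.append(float(np.mean(epoch_losses)))
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{config.epochs}  mean loss {curve[-1]:.4f}")
    recalibrate_batchnorm(
        net,
        [np.asarray(x, dtype=np.float32) for x, _ in dataset],
        config.batch_size,
    )
    return net, LossCurve(losses=curve, task=task, config=config)
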