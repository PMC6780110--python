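"""Class-balanced loss and the training schedule.

Vessel pixels are outnumbered roughly 9:1 by background, so plain
cross-entropy collapses toward the background class.  Training therefore
weights the per-pixel cross-entropy with *median-frequency class balancing*:

    freq_c = (pixels of class c) / (total pixels of images containing c)
    w_c    = median(freq) / freq_c

The published schedule is Adam (denominator epsilon 1e-6) at a constant
learning rate of 5e-4, mini-batches of 7 images with partial final batches
dropped, 15 epochs, images reshuffled each epoch, and gradient clipping by
global L2 norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import SamplePair
from .network import VessNet
from .plan import NetworkPlan

__all__ = [
    "TrainConfig",
    "ClassWeights",
    "class_frequencies",
    "median_frequency_weights",
    "weighted_cross_entropy",
    "Adam",
    "train",
]


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 7
    epochs: int = 15
    moment_epsilon: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    grad_clip: float = 1.0  # global L2-norm threshold
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive")


@dataclass(frozen=True)
class ClassWeights:
    weights: np.ndarray  # one positive weight per class

    def __post_init__(self) -> None:
        if (np.asarray(self.weights) <= 0).any():
            raise ValueError("class weights must be positive")


def class_frequencies(masks: list[np.ndarray], num_classes: int = 2) -> np.ndarray:
    """Per-class pixel frequency.

    The denominator for class c counts pixels only of the images in which
    class c appears at all, the convention of median-frequency balancing.
    """
    if not masks:
        raise ValueError("no masks given")
    counts = np.zeros(num_classes, dtype=np.int64)
    denom = np.zeros(num_classes, dtype=np.int64)
    for m in masks:
        m = np.asarray(m)
        for c in range(num_classes):
            n = int((m == c).sum())
            counts[c] += n
            if n > 0:
                denom[c] += m.size
    if (denom == 0).any():
        missing = int(np.flatnonzero(denom == 0)[0])
        raise ValueError(f"class {missing} absent from every mask")
    return counts / denom


def median_frequency_weights(freqs: np.ndarray) -> ClassWeights:
    """w_c = median(freqs) / freq_c."""
    freqs = np.asarray(freqs, dtype=np.float64)
    if (freqs <= 0).any():
        raise ValueError("zero class frequency")
    return ClassWeights(np.median(freqs) / freqs)


def weighted_cross_entropy(
    prob_map: np.ndarray,
    target_mask: np.ndarray,
    weights: ClassWeights | np.ndarray | None = None,
    eps: float = 1e-12,
) -> float:
    """Mean over pixels of -w_{c(p)} * log p_{c(p)}.

    ``prob_map`` is (..., C, H, W) normalized per pixel; ``target_mask`` the
    integer class map of matching spatial shape.
    """
    p = np.asarray(prob_map)
    t = np.asarray(target_mask)
    if p.ndim == 3:
        p, t = p[None], t[None]
    if p.shape[0] != t.shape[0] or p.shape[2:] != t.shape[1:]:
        raise ValueError(f"shape mismatch: probs {p.shape}, target {t.shape}")
    w = np.ones(p.shape[1]) if weights is None else np.asarray(
        weights.weights if isinstance(weights, ClassWeights) else weights
    )
    picked = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    return float(np.mean(-w[t] * np.log(np.clip(picked, eps, None))))


def _loss_and_dlogits(probs, targets, w):
    """Weighted softmax cross-entropy and its pre-softmax gradient."""
    n, c, h, wd = probs.shape
    npix = n * h * wd
    picked = np.take_along_axis(probs, targets[:, None], axis=1)[:, 0]
    wt = w[targets]
    loss = float(np.mean(-wt * np.log(np.clip(picked, 1e-12, None))))
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, targets[:, None], 1.0, axis=1)
    dlogits = (probs - onehot) * wt[:, None] / npix
    return loss, dlogits.astype(probs.dtype, copy=False)


class Adam:
    """Adam with bias correction; epsilon sits in the update denominator."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-6):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def clip_global_norm(grads: dict, threshold: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``threshold``."""
    total = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
    if threshold > 0 and total > threshold:
        scale = threshold / total
        for k in grads:
            grads[k] = grads[k] * scale
    return total


def _to_batch(pairs: list[SamplePair]):
    x = np.stack([p.image for p in pairs]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    t = np.stack([p.mask for p in pairs]).astype(np.int64)
    return x, t


def train(
    plan: NetworkPlan,
    dataset: list[SamplePair],
    config: TrainConfig | None = None,
    class_weights: ClassWeights | None = None,
) -> tuple[VessNet, list[dict]]:
    """Train a Vess-Net on a SamplePair dataset.

    Returns the trained network and a per-epoch history of mean mini-batch
    loss and pixel accuracy.  Deterministic for a fixed config seed.  Class
    weights default to median-frequency balancing computed once from the
    training masks.  Raises if the dataset is empty or the loss goes
    non-finite.
    """
    config = config or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    if class_weights is None:
        class_weights = median_frequency_weights(
            class_frequencies([p.mask for p in dataset], plan.num_classes)
        )
    w = np.asarray(class_weights.weights, dtype=np.float64)

    net = VessNet(plan, seed=config.seed)
    opt = Adam(
        net.params,
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.moment_epsilon,
    )
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    nbatch = n // config.batch_size  # partial final batch dropped
    if nbatch == 0:
        raise ValueError(
            f"dataset of {n} smaller than one mini-batch ({config.batch_size})"
        )
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        losses, accs = [], []
        for b in range(nbatch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            x, t = _to_batch([dataset[i] for i in idx])
            loss, probs, grads = net.forward_backward(
                x, lambda p: _loss_and_dlogits(p, t, w)
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, batch {b + 1}"
                )
            clip_global_norm(grads, config.grad_clip)
            opt.step(net.params, grads)
            losses.append(loss)
            accs.append(float((probs.argmax(axis=1) == t).mean()))
        history.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.mean(losses)),
                "accuracy": float(np.mean(accs)),
            }
        )
    return net, history
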