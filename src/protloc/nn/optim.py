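"""Adam optimizer and binary cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam", "binary_cross_entropy", "bce_grad"]

_EPS = 1e-7  # probability clipping for the log terms


class Adam:
    """Adam with bias correction (first/second moment decay beta1/beta2)."""

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1.0e-8,
    ):
        self.params = params
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.epsilon)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def binary_cross_entropy(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy over all output elements.

    Works for both the 13-vector confidences of the CNN and the
    (13, H, W) heatmap stacks of the FCN; predictions are clipped away
    from {0, 1} before taking logs.
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def bce_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Gradient of mean BCE w.r.t. the (sigmoid) predictions."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return (p - target) / (p * (1.0 - p)) / pred.size
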