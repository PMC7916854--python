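"""Minimal CPU layer library with explicit backpropagation.

All layers operate on float64 arrays in NCHW layout (images) or NF layout
(flattened features).  Each layer implements ``forward(x, train)`` and
``backward(grad)``; parameters are exposed through ``params()`` as mutable
:class:`Param` records so an optimizer can update them in place.

Convolutions use im2col + GEMM; the input gradient is computed as a
correlation of the output gradient with the spatially flipped, channel-
transposed kernels, so the same im2col machinery serves both directions.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReLU",
    "Sigmoid",
    "BatchNorm2d",
    "MaxPool2d",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "glorot_uniform",
]


class Param:
    """A trainable tensor together with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization: U(-a, a), a = sqrt(6/(fan_in+fan_out))."""
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H_out*W_out, C*k*k) with stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows: (N, C, H_out, W_out, k, k)
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    """2-D convolution (cross-correlation), stride 1, 'same' zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.k = kernel_size
        fan_in = in_ch * kernel_size * kernel_size
        fan_out = out_ch * kernel_size * kernel_size
        w = glorot_uniform(rng, (out_ch, in_ch, kernel_size, kernel_size), fan_in, fan_out)
        self.w = Param("conv_w", w)
        self.b = Param("conv_b", np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        pad = self.k // 2
        cols = _im2col(x, self.k, pad)
        if train:
            self._cols = cols
            self._shape = x.shape
        wmat = self.w.value.reshape(self.out_ch, -1).T  # (C*k*k, out)
        y = cols @ wmat + self.b.value
        return y.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = self._shape
        gflat = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)  # (N*H*W, out)
        self.w.grad += (gflat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += gflat.sum(axis=0)
        # dx = grad correlated with flipped kernels, channels transposed
        wflip = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (in, out, k, k)
        gcols = _im2col(grad, self.k, self.k // 2)
        dx = gcols @ wflip.reshape(self.in_ch, -1).T
        self._cols = None
        return dx.reshape(n, h, w, self.in_ch).transpose(0, 3, 1, 2)

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param("bn_gamma", np.ones(channels))
        self.beta = Param("bn_beta", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._xhat, self._inv = xhat, inv
            return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv[None, :, None, None]
        return dx

    def params(self):
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return y

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(out, self._idx[..., None], grad[..., None], axis=-1)
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Param("dense_w", glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim))
        self.b = Param("dense_b", np.zeros(out_dim))

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self.rate == 0.0:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def __iter__(self):
        return iter(self.layers)
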