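"""Minimal convolutional network core with explicit backpropagation.

Implements exactly the pieces the two FISH models need — 2-D convolution
(im2col), leaky ReLU, global average pooling, a linear head and the Adam
optimizer — in plain numpy with hand-derived gradients.  All computation is
float32, single-threaded and deterministic given the initialization RNG,
which is what lets training runs be reproduced bit-for-bit in tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "LeakyReLU", "Linear", "GlobalAvgPool", "Sequential", "Adam"]


class Param:
    """A trainable array with its accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 / 1x1 convolution over NCHW input, He-initialized, 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s][:, :, :ho, :wo]
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        wm = self.W.value.reshape(-1, c * k * k)
        y = cols @ wm.T + self.b.value
        if train:
            self._cache = (cols, (n, c, h, w), (ho, wo))
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w), (ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        c_out = grad.shape[1]
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        self.W.grad += (g2.T @ cols).reshape(self.W.value.shape)
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.reshape(c_out, -1)).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / c_in)
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in)))
        self.b = Param(np.zeros(c_out))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(layers: Layer) -> list[np.ndarray]:
    """Snapshot all parameter arrays (copies)."""
    return [p.value.copy() for p in layers.params()]


def set_state(layers: Layer, state: list[np.ndarray]) -> None:
    for p, s in zip(layers.params(), state):
        p.value[...] = s
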