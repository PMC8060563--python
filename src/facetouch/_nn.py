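"""Minimal NumPy neural-network core for the 1D-CNN classifier.

Implements exactly the layer zoo the face-touch model needs -- valid-padding
1D convolution, batch normalization, max pooling, inverted dropout, dense
layers, ReLU/softmax -- with hand-derived backward passes and an Adam
optimizer.  Everything is float32 and driven by a single
``numpy.random.Generator`` so that training is bit-reproducible.

Tensors are channels-last: convolutional activations are (n, T, C) and dense
activations (n, D).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Layer:
    """Base class: ``params``/``grads`` are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid-padding temporal convolution; weight layout (k * C_in, F)."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.c_in = in_channels
        self.f = filters
        self.k = kernel_size
        fan_in = kernel_size * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, filters))
        self.params = [w.astype(F32), np.zeros(filters, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def out_length(self, t: int) -> int:
        return t - self.k + 1

    def forward(self, x, training, rng):
        n, t, c = x.shape
        if t < self.k:
            raise ValueError(f"input length {t} < kernel size {self.k}")
        cols = sliding_window_view(x, self.k, axis=1)        # (n, To, C, k)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))  # (n, To, k, C)
        self._cols = cols.reshape(n, t - self.k + 1, self.k * c)
        return self._cols @ self.params[0] + self.params[1]

    def backward(self, dy):
        n, to, f = dy.shape
        cols2 = self._cols.reshape(-1, self.k * self.c_in)
        self.grads[0][...] = cols2.T @ dy.reshape(-1, f)
        self.grads[1][...] = dy.sum(axis=(0, 1))
        dx = np.zeros((n, to + self.k - 1, self.c_in), dtype=dy.dtype)
        w = self.params[0].reshape(self.k, self.c_in, self.f)
        for j in range(self.k):
            dx[:, j : j + to, :] += dy @ w[j].T
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim))
        self.params = [w.astype(F32), np.zeros(out_dim, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class BatchNorm(Layer):
    """Normalizes over every axis but the last (per feature channel)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = [np.ones(channels, dtype=F32), np.zeros(channels, dtype=F32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(x.dtype)
        self._xhat = (x - mean) / self._std
        self._m = x.size // x.shape[-1]
        return self.params[0] * self._xhat + self.params[1]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        g, m = self.params[0], self._m
        return (g / (m * self._std)) * (
            m * dy - dy.sum(axis=axes) - self._xhat * (dy * self._xhat).sum(axis=axes)
        )


class MaxPool1D(Layer):
    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.p = pool_size

    def out_length(self, t: int) -> int:
        return t // self.p

    def forward(self, x, training, rng):
        n, t, c = x.shape
        t2 = (t // self.p) * self.p
        self._t_in = t
        xr = x[:, :t2].reshape(n, t2 // self.p, self.p, c)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        n, to, c = dy.shape
        dx = np.zeros((n, to, self.p, c), dtype=dy.dtype)
        ii, tt, cc = np.ogrid[:n, :to, :c]
        dx[ii, tt, self._arg, cc] = dy
        dx = dx.reshape(n, to * self.p, c)
        if self._t_in > to * self.p:
            pad = np.zeros((n, self._t_in - to * self.p, c), dtype=dy.dtype)
            dx = np.concatenate([dx, pad], axis=1)
        return dx


class Dropout(Layer):
    """Inverted dropout; ``rate`` is the fraction of units dropped."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Softmax(Layer):
    def forward(self, x, training, rng):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dy):
        p = self._p
        return p * (dy - (dy * p).sum(axis=-1, keepdims=True))


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Network:
    """A plain layer stack with shared parameter/gradient bookkeeping."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(probs, eps, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=-1).mean())


def softmax_xent_grad(logits: np.ndarray, onehot: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Fused softmax + cross-entropy: returns (probs, dlogits, loss)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    loss = cross_entropy(p, onehot)
    return p, (p - onehot) / logits.shape[0], loss


def normalize_probs(x: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """Turn non-negative scores into probabilities by L1 normalization."""
    q = np.maximum(x, 0) + eps
    return q / q.sum(axis=-1, keepdims=True)


def normalized_xent_grad(x: np.ndarray, onehot: np.ndarray, eps: float = 1e-7) -> tuple[np.ndarray, np.ndarray, float]:
    """Cross-entropy through L1 normalization of non-negative scores.

    Used by the ``softmax_hidden`` activation layout whose output layer is a
    ReLU rather than a softmax.
    """
    q = np.maximum(x, 0) + eps
    s = q.sum(axis=-1, keepdims=True)
    p = q / s
    loss = cross_entropy(p, onehot)
    n = x.shape[0]
    dp = -(onehot / np.clip(p, eps, None)) / n
    dq = (dp - (dp * p).sum(axis=-1, keepdims=True)) / s
    dx = np.where(x > 0, dq, 0.0)
    return p, dx, loss
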