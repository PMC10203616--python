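"""Minimal NumPy neural-network primitives for the dual-input classifier.

No deep-learning framework is assumed at runtime, so the handful of layer
types the architecture needs (2-D valid convolution, batch normalization,
2x2/stride-1 max pooling, dense, dropout) are implemented here with
explicit forward/backward passes, plus an Adagrad optimizer and an MSE
loss on softmax outputs. Data layout is NHWC; everything is float64 and
fully deterministic given the RNG passed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adagrad",
    "softmax",
    "mse_softmax_loss_and_grad",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: stateless unless it declares ``params``/``grads``."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def regularization_loss(self) -> float:
        return 0.0


class Conv2D(Layer):
    """Valid-padding, stride-1 2-D convolution (cross-correlation), NHWC."""

    def __init__(self, in_channels: int, filters: int, kernel: tuple[int, int], rng: np.random.Generator):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        fan_out = filters * kh * kw
        self.kernel = kernel
        self.w = glorot_uniform(rng, (kh, kw, in_channels, filters), fan_in, fan_out)
        self.b = np.zeros(filters)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        kh, kw = self.kernel
        n, h, w_, c = x.shape
        oh, ow = h - kh + 1, w_ - kw + 1
        # windows: (n, oh, ow, c, kh, kw) -> columns (n*oh*ow, kh*kw*c)
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, kh * kw * c)
        wmat = self.w.reshape(kh * kw * c, -1)
        out = cols @ wmat + self.b
        if training:
            self._cols = cols
            self._x_shape = x.shape
        return out.reshape(n, oh, ow, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        n, h, w_, c = self._x_shape
        oh, ow = h - kh + 1, w_ - kw + 1
        gflat = grad.reshape(n * oh * ow, -1)
        self.dw[...] = (self._cols.T @ gflat).reshape(self.w.shape)
        self.db[...] = gflat.sum(axis=0)
        dcols = (gflat @ self.w.reshape(kh * kw * c, -1).T).reshape(n, oh, ow, kh, kw, c)
        dx = np.zeros(self._x_shape)
        for i in range(kh):
            for j in range(kw):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j, :]
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def grads(self) -> list[np.ndarray]:
        return [self.dgamma, self.dbeta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._xhat = (x - mean) / np.sqrt(var + self.eps)
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._m = int(np.prod([x.shape[a] for a in axes]))
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(self.running_var + self.eps) + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = tuple(range(grad.ndim - 1))
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        m = self._m
        dxhat = grad * self.gamma
        return (
            self._istd
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 1 (overlapping windows), NHWC."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w_, c = x.shape
        win = sliding_window_view(x, (2, 2), axis=(1, 2))  # (n, oh, ow, c, 2, 2)
        flat = win.reshape(n, h - 1, w_ - 1, c, 4)
        out = flat.max(axis=-1)
        if training:
            self._argmax = flat.argmax(axis=-1)
            self._x_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w_, c = self._x_shape
        oh, ow = h - 1, w_ - 1
        dx = np.zeros(self._x_shape)
        for k in range(4):
            i, j = divmod(k, 2)
            contrib = grad * (self._argmax == k)
            dx[:, i : i + oh, j : j + ow, :] += contrib
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with optional L2 kernel penalty (loss += l2 * sum(w^2))."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, l2: float = 0.0):
        self.w = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = np.zeros(out_dim)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.l2 = l2

    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw[...] = self._x.T @ grad
        if self.l2:
            self.dw += 2.0 * self.l2 * self.w
        self.db[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def regularization_loss(self) -> float:
        return float(self.l2 * np.sum(self.w**2))


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def regularization_loss(self) -> float:
        return sum(layer.regularization_loss() for layer in self.layers)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mse_softmax_loss_and_grad(logits: np.ndarray, y_onehot: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """MSE between softmax(logits) and one-hot targets.

    Returns (loss, probabilities, gradient w.r.t. logits). The loss is the
    mean over batch and output dimensions of the squared error.
    """
    p = softmax(logits)
    diff = p - y_onehot
    loss = float(np.mean(diff**2))
    dldp = 2.0 * diff / diff.size
    # Softmax Jacobian: dz_k = p_k * (dldp_k - sum_j dldp_j p_j)
    dz = p * (dldp - (dldp * p).sum(axis=-1, keepdims=True))
    return loss, p, dz


class Adagrad:
    """Adagrad with per-parameter accumulated squared gradients."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float = 0.01,
                 initial_accumulator: float = 0.1, eps: float = 1e-7):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.eps = eps
        self.acc = [np.full_like(p, initial_accumulator) for p in params]

    def step(self) -> None:
        for p, g, a in zip(self.params, self.grads, self.acc):
            a += g**2
            p -= self.lr * g / (np.sqrt(a) + self.eps)
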