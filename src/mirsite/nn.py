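"""Minimal feed-forward neural-network layers with exact backprop.

Self-contained numpy building blocks -- 2-D convolution (size-preserving
padding), ReLU, 2x2 max-pooling (floor semantics), inverted dropout, dense
layers, a fused sigmoid / binary-cross-entropy head, and Adam -- sized for
the small 25x25 multi-channel inputs this package trains on.  Everything is
single-threaded and deterministic given a seeded generator: weight
initialization, minibatch order, and dropout masks all draw from an
explicitly passed ``numpy.random.Generator``.

Layers expose ``forward(x, training, rng)`` / ``backward(grad)`` and a
``params()`` list of :class:`Param`; gradients are validated against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv2D", "ReLU", "MaxPool2", "Dropout", "Flatten",
    "Dense", "Sequential", "Adam", "sigmoid", "bce_loss_and_grad",
]


class Param:
    """A trainable tensor and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list:
        return []

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution with same (zero) padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        # He-normal init for ReLU networks
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(fan_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        B, C, H, W = x.shape
        if self.k > H or self.k > W:
            raise ValueError(f"kernel {self.k} larger than input {H}x{W}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B, H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, -1)
        self._cache = (cols, (B, C, H, W))
        y = cols @ self.w.value + self.b.value
        return y.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, (B, C, H, W) = self._cache
        g = grad.transpose(0, 2, 3, 1).reshape(B, H * W, self.c_out)
        self.w.grad += np.einsum("bnf,bno->fo", cols, g)
        self.b.grad += g.sum(axis=(0, 1))
        dcols = (g @ self.w.value.T).reshape(B, H, W, C, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p))
        for a in range(self.k):
            for b in range(self.k):
                dxp[:, :, a:a + H, b:b + W] += dcols[:, :, :, :, a, b] \
                    .transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max-pooling with stride 2 and floor semantics (25 -> 12)."""

    def forward(self, x, training=False, rng=None):
        B, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, :, : 2 * Ho, : 2 * Wo]
        win = xc.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(B, C, Ho, Wo, 4)
        self._arg = np.argmax(win, axis=-1)
        self._shape = (B, C, H, W)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        B, C, H, W = self._shape
        Ho, Wo = H // 2, W // 2
        dwin = np.zeros((B, C, Ho, Wo, 4))
        np.put_along_axis(dwin, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros((B, C, H, W))
        dx[:, :, : 2 * Ho, : 2 * Wo] = dwin.reshape(B, C, Ho, Wo, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(B, C, 2 * Ho, 2 * Wo)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / n_in),
                                  size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False, rng=None):
        for l in self.layers:
            x = l.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        c1 = 1 - self.beta1 ** self.t
        c2 = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.beta1) * (p.grad - m)
            v += (1 - self.beta2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy on logits and its gradient (fused sigmoid)."""
    p = sigmoid(logits)
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    loss = float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))
    grad = (p - y) / len(y)
    return loss, grad, p
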