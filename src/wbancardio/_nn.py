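"""Minimal numpy neural-network kernel used by the feature extractors.

Implements just what the package needs — dense and 1-D convolution layers,
ReLU, Adam, and the two losses — with explicit forward/backward passes.
Shapes: dense layers take ``[n, d]``; convolutions take ``[n, L, C]``
(batch, sequence length, channels). Gradients are exact (verified against
numerical differentiation in the test suite).
"""

from __future__ import annotations

import numpy as np


class TrainingDivergence(RuntimeError):
    """Raised when a training loss becomes non-finite."""


class Adam:
    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, weight_decay: float = 0.0) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if weight_decay:
                g = g + weight_decay * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Conv1D:
    """Valid (no-padding) stride-1 1-D convolution, [n, L, Cin] -> [n, L-k+1, Cout]."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        self.k = kernel_size
        fan_in = kernel_size * c_in
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.W = rng.uniform(-limit, limit, size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x):
        n, L, c = x.shape
        lo = L - self.k + 1
        cols = np.empty((n, lo, self.k * c), dtype=x.dtype)
        for j in range(lo):
            cols[:, j, :] = x[:, j : j + self.k, :].reshape(n, self.k * c)
        return cols

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.W + self.b

    def backward(self, dout):
        n, L, c = self._x_shape
        lo = L - self.k + 1
        cols2d = self._cols.reshape(-1, self.k * c)
        self.grads[0][...] = cols2d.T @ dout.reshape(-1, dout.shape[-1])
        self.grads[1][...] = dout.sum(axis=(0, 1))
        dcols = dout @ self.W.T  # [n, lo, k*c]
        dx = np.zeros((n, L, c), dtype=dout.dtype)
        for j in range(lo):
            dx[:, j : j + self.k, :] += dcols[:, j, :].reshape(n, self.k, c)
        return dx


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, upto: int | None = None):
        for layer in self.layers[:upto]:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def mse_loss(pred, target):
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


def bce_with_logits(logits, y, sample_weight=None):
    """Binary cross-entropy on raw logits; returns (mean loss, dloss/dlogits).

    ``sample_weight`` rescales each term (e.g. inverse class frequency to
    counter label imbalance); weights are applied as-is, so pass weights that
    average to 1 to keep the loss scale comparable.
    """
    logits = logits.reshape(-1)
    y = y.reshape(-1)
    per = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    p = 1.0 / (1.0 + np.exp(-logits))
    grad = p - y
    if sample_weight is not None:
        per = per * sample_weight
        grad = grad * sample_weight
    return float(np.mean(per)), (grad / y.size).reshape(-1, 1)


def balanced_weights(y) -> np.ndarray:
    """Inverse-class-frequency sample weights, normalized to mean 1."""
    y = np.asarray(y).reshape(-1)
    n_pos = y.sum()
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return np.ones_like(y, dtype=float)
    w = np.where(y == 1, y.size / (2.0 * n_pos), y.size / (2.0 * n_neg))
    return w


def check_finite(loss: float) -> None:
    if not np.isfinite(loss):
        raise TrainingDivergence(f"training loss diverged (loss={loss})")
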