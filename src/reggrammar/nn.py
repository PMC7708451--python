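"""Minimal CPU neural-network engine for the sequence-expression models.

Implements exactly the pieces the CNN-FC architecture needs — 1-D
convolution (im2col), batch normalization, ReLU, max-pooling, inverted
dropout, dense layers, an optional softmax head and the Adam optimizer —
with hand-written backpropagation. Weight initialization is uniform
(Glorot-style bounds) and every stochastic element (init, dropout,
shuffling) draws from generators seeded by the caller, so training is
bit-reproducible on a fixed thread count.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _uniform_init(shape: tuple[int, ...], fan_in: int, fan_out: int,
                  rng: np.random.Generator, dtype) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv1D(Layer):
    """Valid-mode 1-D convolution on (batch, channels, length) input."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        if filters <= 0 or kernel <= 0:
            raise ValueError("filters and kernel size must be positive")
        self.kernel = kernel
        self.W = _uniform_init((filters, in_channels, kernel),
                               in_channels * kernel, filters, rng, dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        B, C, L = x.shape
        K = self.kernel
        if L < K:
            raise ValueError(f"input length {L} shorter than kernel {K}")
        cols = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)
        # (B, C, L_out, K) -> (B, L_out, C*K)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, L - K + 1, -1)
        self._cols, self._in_shape = cols, x.shape
        F = self.W.shape[0]
        y = cols @ self.W.reshape(F, -1).T + self.b
        return y.transpose(0, 2, 1)  # (B, F, L_out)

    def backward(self, dy):
        B, C, L = self._in_shape
        K = self.kernel
        F = self.W.shape[0]
        dyr = dy.transpose(0, 2, 1).reshape(-1, F)  # (B*L_out, F)
        cols = self._cols.reshape(-1, C * K)
        self.dW[...] = (dyr.T @ cols).reshape(self.W.shape)
        self.db[...] = dyr.sum(axis=0)
        dcols = (dyr @ self.W.reshape(F, -1)).reshape(B, L - K + 1, C, K)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        for k in range(K):
            dx[:, :, k : k + L - K + 1] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization for 2-D (B, D) or 3-D (B, C, L)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    @staticmethod
    def _axes(x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, train):
        axes, sh = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        self._xhat, self._inv, self._n = xhat, inv, x.size // x.shape[1]
        return (self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)).astype(x.dtype)

    def backward(self, dy):
        axes, sh = self._axes(dy), self._shape(dy)
        xhat, inv, n = self._xhat, self._inv, self._n
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        g = self.gamma.reshape(sh)
        dxhat = dy * g
        dx = (inv.reshape(sh) / n) * (
            n * dxhat
            - dxhat.sum(axis=axes).reshape(sh)
            - xhat * (dxhat * xhat).sum(axis=axes).reshape(sh)
        )
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    def __init__(self, width: int):
        if width <= 0:
            raise ValueError("pool width must be positive")
        self.width = width

    def forward(self, x, train):
        B, C, L = x.shape
        w = self.width
        Lp = (L // w) * w
        self._in_shape, self._Lp = x.shape, Lp
        xr = x[:, :, :Lp].reshape(B, C, Lp // w, w)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        B, C, L = self._in_shape
        w = self.width
        # build the pooled-window gradient separately: a reshaped slice of
        # dx may be a copy (non-contiguous when L % w != 0)
        dxr = np.zeros((B, C, self._Lp // w, w), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :, : self._Lp] = dxr.reshape(B, C, self._Lp)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return (x * self._mask).astype(x.dtype)

    def backward(self, dy):
        return dy if self._mask is None else (dy * self._mask).astype(dy.dtype)


class Flatten(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        if out_dim <= 0:
            raise ValueError("layer width must be positive")
        self.W = _uniform_init((in_dim, out_dim), in_dim, out_dim, rng, dtype)
        self.b = np.zeros(out_dim, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Softmax(Layer):
    """Row-wise softmax head (used for codon-probability outputs)."""

    def forward(self, x, train):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, dy):
        y = self._y
        return y * (dy - (dy * y).sum(axis=1, keepdims=True))


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class TwoBranchNet:
    """Sequence branch (conv stack) concatenated with numeric features,
    followed by a fully connected head."""

    def __init__(self, seq_branch: Sequential, head: Sequential, n_numeric: int):
        self.seq_branch, self.head, self.n_numeric = seq_branch, head, n_numeric

    def forward(self, x_seq, x_num, train=False):
        h = self.seq_branch.forward(x_seq, train)
        self._split = h.shape[1]
        z = np.concatenate([h, x_num.astype(h.dtype)], axis=1)
        return self.head.forward(z, train)

    def backward(self, dy):
        dz = self.head.backward(dy)
        return self.seq_branch.backward(dz[:, : self._split])

    def params(self):
        return self.seq_branch.params() + self.head.params()

    def grads(self):
        return self.seq_branch.grads() + self.head.grads()

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
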