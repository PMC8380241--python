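"""Minimal NumPy neural-network layers (NCHW) with exact backward passes.

Only what the dual-path classifier needs: same-padding stride-1
convolutions via im2col, batch normalisation, ReLU, 2x2 max pooling,
global average pooling and a dense head. Parameters are float32; every
layer exposes ``params`` as a list of [value, grad] pairs consumed by the
optimiser.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> list:
        return []


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patches with same zero-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=F32)


class Conv2d(Layer):
    """Same-padding, stride-1 convolution. Weights (C_in*k*k, C_out)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = (rng.standard_normal((fan_in, c_out)) * std).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._params = [[self.w, self.dw], [self.b, self.db]]

    @property
    def params(self):
        return self._params

    def forward(self, x, train):
        n, c, h, w = x.shape
        self._shape = (n, c, h, w)
        if self.k == 1:
            self._cols = x.transpose(0, 2, 3, 1).reshape(-1, c)
        else:
            self._cols = _im2col(x, self.k)
        out = self._cols @ self.w + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c, h, w = self._shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out).astype(F32)
        self.dw[...] = self._cols.T @ dyf
        self.db[...] = dyf.sum(axis=0)
        self._cols = None
        if self.k == 1:
            dx = dyf @ self.w.T
            return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        # dx = full correlation of dy with spatially flipped weights
        wk = self.w.reshape(self.c_in, self.k, self.k, self.c_out)
        w_flip = wk[:, ::-1, ::-1, :].transpose(3, 1, 2, 0).reshape(
            self.c_out * self.k * self.k, self.c_in
        )
        cols_dy = _im2col(dy.astype(F32), self.k)
        dx = cols_dy @ w_flip
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._params = [[self.gamma, self.dgamma], [self.beta, self.dbeta]]

    @property
    def params(self):
        return self._params

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._inv = inv.astype(F32)
        return (self.gamma[None, :, None, None] * self._xhat
                + self.beta[None, :, None, None]).astype(F32)

    def backward(self, dy):
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g_inv = (self.gamma * self._inv)[None, :, None, None]
        sum_dy = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dyx = (dy * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = g_inv * (dy - sum_dy / m - self._xhat * sum_dyx / m)
        self._xhat = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (even spatial dims assumed)."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = (n, c, h, w)
        return out

    def backward(self, dy):
        n, c, h, w = self._shape
        dyr = dy[:, :, :, None, :, None]
        # split gradient among tied maxima to keep the pass exact
        counts = self._mask.sum(axis=(3, 5))[:, :, :, None, :, None]
        dx = (self._mask * dyr / counts).reshape(n, c, h, w)
        self._mask = None
        return dx.astype(F32)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).astype(F32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * std).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._params = [[self.w, self.dw], [self.b, self.db]]

    @property
    def params(self):
        return self._params

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.w.T
        self._x = None
        return dx


class Concat(Layer):
    """Channel concatenation of parallel paths (used by dual-path blocks)."""

    def __init__(self, widths: list[int]):
        self.widths = widths

    def forward_list(self, xs):
        return np.concatenate(xs, axis=1)

    def backward_split(self, dy):
        out, i = [], 0
        for w in self.widths:
            out.append(dy[:, i:i + w])
            i += w
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray,
                       sample_weights: np.ndarray | None = None):
    """Mean weighted cross-entropy loss and gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    ll = -np.log(p[np.arange(n), labels] + eps)
    if sample_weights is None:
        loss = float(ll.mean())
        grad = p
        grad[np.arange(n), labels] -= 1.0
        grad /= n
    else:
        wsum = float(sample_weights.sum())
        loss = float((ll * sample_weights).sum() / wsum)
        grad = p * sample_weights[:, None]
        grad[np.arange(n), labels] -= sample_weights
        grad /= wsum
    return loss, grad.astype(F32)


class Adam:
    """ADAM with coupled L2 regularisation (weight decay added to the gradient)."""

    def __init__(self, params: list, l2: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.l2, self.beta1, self.beta2, self.eps = l2, beta1, beta2, eps
        self.m = [np.zeros_like(p[0]) for p in params]
        self.v = [np.zeros_like(p[0]) for p in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g + self.l2 * p if p.ndim > 1 else g  # no decay on biases/BN shifts
            m += (1 - b1) * (grad - m)
            v += (1 - b2) * (grad * grad - v)
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
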