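"""Minimal 1-D convolutional network primitives with explicit backprop.

Layers operate on arrays shaped (batch, channels, length).  Each layer caches
what its backward pass needs; ``params()`` exposes (name, value, grad) views
consumed by the Adam optimizer.  Gradient correctness is pinned by numerical
finite-difference tests in the suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)


class Conv1d:
    """Same-padded 1-D convolution (odd kernel)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        scale = np.sqrt(2.0 / (cin * k))
        self.W = Param(rng.standard_normal((cout, cin, k)) * scale)
        self.b = Param(np.zeros(cout))
        self.k = k

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = sliding_window_view(xp, self.k, axis=2)  # (N,C,L,k)
        if train:
            self._cols = cols
        y = np.einsum("nclk,ock->nol", cols, self.W.v, optimize=True)
        return y + self.b.v[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.g += np.einsum("nol,nclk->ock", dy, self._cols, optimize=True)
        self.b.g += dy.sum(axis=(0, 2))
        p = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p)))
        cols_dy = sliding_window_view(dyp, self.k, axis=2)  # (N,O,L,k)
        dx = np.einsum("nolk,ock->ncl", cols_dy, self.W.v[:, :, ::-1],
                       optimize=True)
        self._cols = None
        return dx

    def params(self):
        return [self.W, self.b]


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.where(x > 0, x, self.alpha * np.expm1(x))
        if train:
            self._x_pos = x > 0
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * np.where(self._x_pos, 1.0, self._y + self.alpha)

    def params(self):
        return []


class BatchNorm1d:
    """Per-channel normalization over (batch, length) with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            xhat = (x - mean[None, :, None]) / np.sqrt(var + self.eps)[None, :, None]
            self._xhat = xhat
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
        else:
            xhat = (x - self.run_mean[None, :, None]) / np.sqrt(
                self.run_var + self.eps)[None, :, None]
        return self.gamma.v[None, :, None] * xhat + self.beta.v[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        m = dy.shape[0] * dy.shape[2]
        self.gamma.g += (dy * xhat).sum(axis=(0, 2))
        self.beta.g += dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma.v[None, :, None]
        dx = (inv_std[None, :, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2))[None, :, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2))[None, :, None]
        )
        self._xhat = None
        return dx

    def params(self):
        return [self.gamma, self.beta]


class MaxPool2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, l = x.shape
        if l % 2:
            raise ValueError("length must be even for 2x pooling")
        xr = x.reshape(n, c, l // 2, 2)
        idx = xr.argmax(axis=3)
        if train:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, l = self._shape
        dxr = np.zeros((n, c, l // 2, 2))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        return dxr.reshape(n, c, l)

    def params(self):
        return []


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, l = dy.shape
        return dy.reshape(n, c, l // 2, 2).sum(axis=3)

    def params(self):
        return []


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_cross_entropy(logits: np.ndarray, labels: np.ndarray
                         ) -> tuple[float, np.ndarray]:
    """Mean CE over positions with label >= 0; returns (loss, dlogits).

    ``logits`` is (N, T, C), ``labels`` (N, T) with -1 marking masked
    (artifact) positions.
    """
    p = softmax(logits, axis=-1)
    mask = labels >= 0
    n_valid = int(mask.sum())
    if n_valid == 0:
        return 0.0, np.zeros_like(logits)
    safe = np.where(mask, labels, 0)
    picked = np.take_along_axis(p, safe[..., None], axis=-1)[..., 0]
    loss = float(-(np.log(picked + 1e-12) * mask).sum() / n_valid)
    dlogits = p.copy()
    np.put_along_axis(
        dlogits, safe[..., None],
        np.take_along_axis(dlogits, safe[..., None], axis=-1) - 1.0, axis=-1)
    dlogits *= (mask[..., None] / n_valid)
    return loss, dlogits


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.v = [np.zeros_like(p.v) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            v[...] = self.b2 * v + (1 - self.b2) * p.g**2
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
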