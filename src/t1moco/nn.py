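"""Minimal NumPy neural-network layers with explicit backpropagation.

No deep-learning framework is assumed at runtime, so the handful of layer
types the registration network needs — 3x3 convolution, batch
normalisation, leaky ReLU, 2x2 max pooling, stride-2 transposed
convolution, bilinear warping — are implemented here with hand-written
forward/backward passes, plus an Adam optimiser and a reduce-on-plateau
learning-rate scheduler.

All tensors are float32 NCHW. Each layer instance is used at most once per
forward pass and caches what its backward pass needs; ``backward`` must be
called in reverse order of ``forward``. Parameter gradients accumulate into
``Param.grad`` until ``zero_grad``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "LeakyReLU",
    "MaxPool2",
    "ConvTranspose2",
    "warp_features_forward",
    "warp_features_backward",
    "upsample2_forward",
    "upsample2_backward",
    "Adam",
    "ReduceLROnPlateau",
]

_DT = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DT)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> dict[str, np.ndarray]:
        """State that is saved/loaded but not optimised (e.g. BN statistics)."""
        return {}


class Conv2d(Layer):
    """Same-padding 2-D convolution (stride 1) via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        if zero_init:
            w = np.zeros((cout, cin * k * k))
        else:
            scale = np.sqrt(2.0 / (cin * k * k))
            w = (rng or np.random.default_rng()).normal(0.0, scale, (cout, cin * k * k))
        self.w = Param(w)
        self.b = Param(np.zeros(cout))
        self._cols = None
        self._in_shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w_ = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w_, c * k * k)
        y = cols @ self.w.value.T + self.b.value
        self._cols = cols
        self._in_shape = x.shape
        return np.ascontiguousarray(y.reshape(n, h, w_, self.cout).transpose(0, 3, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w_ = self._in_shape
        k, p = self.k, self.pad
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.w.grad += g.T @ self._cols
        self.b.grad += g.sum(axis=0)
        gcols = (g @ self.w.value).reshape(n, h, w_, c, k, k)
        gxp = np.zeros((n, c, h + 2 * p, w_ + 2 * p), dtype=_DT)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + h, j:j + w_] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return gxp[:, :, p:p + h, p:p + w_] if p else gxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=_DT)
        self.running_var = np.ones(c, dtype=_DT)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_buffers(self, bufs: dict[str, np.ndarray]):
        self.running_mean = np.asarray(bufs["running_mean"], dtype=_DT)
        self.running_var = np.asarray(bufs["running_var"], dtype=_DT)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(_DT)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(_DT)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std.astype(_DT))
        return (self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]).astype(_DT)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = gy.shape[0] * gy.shape[2] * gy.shape[3]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gy.sum(axis=(0, 2, 3))
        gxhat = gy * self.gamma.value[None, :, None, None]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv_std[None, :, None, None]
        return gx.astype(_DT)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, gy, self.slope * gy)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        self._cache = None
        gxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=_DT)
        np.put_along_axis(gxr, idx[..., None], gy[..., None].astype(_DT), axis=-1)
        return gxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class ConvTranspose2(Layer):
    """2x2, stride-2 transposed convolution (exact 2x upsampling, no overlap)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        scale = np.sqrt(2.0 / cin)
        self.w = Param((rng or np.random.default_rng()).normal(0.0, scale, (cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        y6 = np.einsum("nihw,ioab->nohawb", x, self.w.value, optimize=True)
        y = y6.reshape(n, -1, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        if train:
            self._x = x
        return y.astype(_DT)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        n, co, H, W = gy.shape
        gy6 = gy.reshape(n, co, H // 2, 2, W // 2, 2)
        self.w.grad += np.einsum("nihw,nohawb->ioab", x, gy6, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2, 3))
        return np.einsum("nohawb,ioab->nihw", gy6, self.w.value, optimize=True).astype(_DT)


# ---------------------------------------------------------------------------
# warping layer (bilinear gather / splat)
# ---------------------------------------------------------------------------

def warp_features_forward(feats: np.ndarray, flows: np.ndarray):
    """Backward-warp feature maps by per-item displacement fields.

    ``feats``: (N, C, H, W); ``flows``: (N, 2, H, W) in pixels (row, col),
    same backward-map convention as :func:`t1moco.dvf.warp`, constant-zero
    fill outside the domain. Returns ``(warped, cache)``; gradients flow to
    the features only (flow coordinates are treated as constants, which is
    sufficient because every scale's field has its own supervision).
    """
    n, c, h, w = feats.shape
    gr, gc = np.meshgrid(np.arange(h, dtype=_DT), np.arange(w, dtype=_DT), indexing="ij")
    rows = gr[None] + flows[:, 0]
    cols = gc[None] + flows[:, 1]
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    dr = (rows - r0).astype(_DT)
    dc = (cols - c0).astype(_DT)
    out = np.zeros_like(feats)
    cache = []
    flat = feats.reshape(n, c, h * w)
    for (ri, ci, wgt) in (
        (r0, c0, (1 - dr) * (1 - dc)),
        (r0, c0 + 1, (1 - dr) * dc),
        (r0 + 1, c0, dr * (1 - dc)),
        (r0 + 1, c0 + 1, dr * dc),
    ):
        valid = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
        lin = np.clip(ri, 0, h - 1) * w + np.clip(ci, 0, w - 1)  # (n, h, w)
        wv = (wgt * valid).astype(_DT)
        out += np.take_along_axis(flat, lin.reshape(n, 1, -1), axis=2).reshape(n, c, h, w) * wv[:, None]
        cache.append((lin.reshape(n, -1), wv.reshape(n, -1)))
    return out, ((n, c, h, w), cache)


def warp_features_backward(gy: np.ndarray, cache) -> np.ndarray:
    """Adjoint of the gather: splat ``gy`` back onto the source grid."""
    (n, c, h, w), corners = cache
    gx = np.zeros((n, c, h * w), dtype=_DT)
    gyf = gy.reshape(n, c, h * w)
    hw = h * w
    for lin, wv in corners:
        weighted = gyf * wv[:, None, :]  # (n, c, hw)
        # per-(item, channel) scatter-add via bincount on flattened indices
        offs = (np.arange(n, dtype=np.int64) * hw)[:, None]
        idx = (lin + offs).ravel()
        for ch in range(c):
            gx[:, ch, :] += np.bincount(idx, weights=weighted[:, ch, :].ravel().astype(np.float64),
                                        minlength=n * hw).reshape(n, hw).astype(_DT)
    return gx.reshape(n, c, h, w)


def upsample2_forward(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling of a displacement tensor with the
    displacement values doubled (pixel units follow the grid)."""
    return 2.0 * np.repeat(np.repeat(x, 2, axis=-2), 2, axis=-1)


def upsample2_backward(gy: np.ndarray) -> np.ndarray:
    n4 = gy.shape[:-2]
    H, W = gy.shape[-2:]
    g = gy.reshape(*n4, H // 2, 2, W // 2, 2).sum(axis=(-3, -1))
    return (2.0 * g).astype(_DT)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10,
                 min_lr: float = 1e-5, min_delta: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> float:
        if metric < self.best - self.min_delta:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.opt.lr
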