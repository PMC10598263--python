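"""Minimal layer library: forward/backward passes on NumPy arrays.

Every layer is stateless between batches except for caches written during
``forward`` and consumed by ``backward``. Arrays are float32 throughout;
gradients are accumulated into ``.grads`` aligned with ``.params``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "LeakyReLU",
    "Flatten",
    "Dense",
    "Dropout",
    "he_uniform",
]


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Fan-in-scaled uniform initialization: U(-sqrt(6/fan_in), +sqrt(6/fan_in))."""
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Layer:
    """Base layer; parameter-free layers inherit the empty param lists."""

    params: list  # list of np.ndarray (mutated in place by the optimizer)
    grads: list   # matching gradient arrays, refreshed each backward pass
    weight_flags: list  # True where L2 decay applies (weights, not biases)

    def __init__(self):
        self.params = []
        self.grads = []
        self.weight_flags = []

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv2D(Layer):
    """2D convolution (cross-correlation), 'valid' padding, square kernel.

    Stride-1 convolutions run through cache-blocked numba kernels when
    numba is importable; other strides (and numba-free environments) fall
    back to im2col + GEMM. When the layer is the first in a network,
    ``skip_input_grad`` suppresses the useless input-gradient pass.
    """

    def __init__(self, in_channels, out_channels, kernel, stride=1, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.skip_input_grad = False
        fan_in = in_channels * kernel * kernel
        rng = rng or np.random.default_rng()
        self.W = he_uniform(rng, (out_channels, in_channels, kernel, kernel), fan_in)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.weight_flags = [True, False]

    def _fast(self) -> bool:
        from ._kernels import HAVE_NUMBA

        return HAVE_NUMBA and self.stride == 1

    def _buf(self, name, shape, dtype=np.float32):
        buf = getattr(self, name, None)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=dtype)
            setattr(self, name, buf)
        return buf

    def forward(self, x, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=np.float32)
        if self._fast():
            from ._kernels import conv2d_fwd

            self._cache = ("x", x)
            B, C, H, Wd = x.shape
            k = self.kernel
            y = self._buf("_ybuf", (B, self.out_channels, H - k + 1, Wd - k + 1))
            conv2d_fwd(x, self.W, self.b, y)
            return y
        k, s = self.kernel, self.stride
        B, C, H, W = x.shape
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        # (B, Ho, Wo, C*k*k) contiguous copy for the GEMM
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
        Wmat = self.W.reshape(self.out_channels, -1)
        y = cols @ Wmat.T + self.b
        self._cache = ("cols", (x.shape, cols))
        return y.reshape(B, Ho, Wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy):
        kind, payload = self._cache
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        if kind == "x":
            from ._kernels import conv2d_bwd_dw, conv2d_bwd_dx

            x = payload
            dW, db = conv2d_bwd_dw(x, dy, self.kernel)
            self.grads[0][...] = dW
            self.grads[1][...] = db
            self._cache = None
            if self.skip_input_grad:
                return None
            dx = self._buf("_dxbuf", x.shape)
            conv2d_bwd_dx(self.W, dy, dx)
            return dx
        k, s = self.kernel, self.stride
        (B, C, H, W), cols = payload
        _, F, Ho, Wo = dy.shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, F)
        Wmat = self.W.reshape(F, -1)
        self.grads[0][...] = (dy_mat.T @ cols).reshape(self.W.shape)
        self.grads[1][...] = dy_mat.sum(axis=0)
        self._cache = None
        if self.skip_input_grad:
            return None
        dcols = (dy_mat @ Wmat).reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols[..., i, j]
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped (floor division), matching the usual framework default."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def _pbuf(self, name, shape, dtype):
        buf = getattr(self, name, None)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=dtype)
            setattr(self, name, buf)
        return buf

    def forward(self, x, training=False, rng=None):
        from ._kernels import HAVE_NUMBA

        p = self.pool
        if HAVE_NUMBA:
            from ._kernels import maxpool_fwd

            x = np.ascontiguousarray(x, dtype=np.float32)
            B, C, H, W = x.shape
            out_shape = (B, C, H // p, W // p)
            y = self._pbuf("_ybuf", out_shape, np.float32)
            idx = self._pbuf("_ibuf", out_shape, np.int32)
            maxpool_fwd(x, p, y, idx)
            self._cache = ("numba", (x.shape, idx))
            return y
        B, C, H, W = x.shape
        Ho, Wo = H // p, W // p
        xr = x[:, :, : Ho * p, : Wo * p].reshape(B, C, Ho, p, Wo, p)
        xp = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, p * p)
        idx = xp.argmax(axis=-1)
        y = np.take_along_axis(xp, idx[..., None], axis=-1)[..., 0]
        self._cache = ("numpy", (x.shape, idx))
        return y

    def backward(self, dy):
        p = self.pool
        kind, ((B, C, H, W), idx) = self._cache
        if kind == "numba":
            from ._kernels import maxpool_bwd

            self._cache = None
            dx = self._pbuf("_dxbuf", (B, C, H, W), np.float32)
            maxpool_bwd(np.ascontiguousarray(dy, dtype=np.float32), idx, dx, p)
            return dx
        Ho, Wo = H // p, W // p
        dxp = np.zeros((B, C, Ho, Wo, p * p), dtype=np.float32)
        np.put_along_axis(dxp, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((B, C, H, W), dtype=np.float32)
        dx[:, :, : Ho * p, : Wo * p] = (
            dxp.reshape(B, C, Ho, Wo, p, p).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * p, Wo * p)
        )
        self._cache = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, training=False, rng=None):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy):
        dx = np.where(self._neg, self.slope * dy, dy)
        self._neg = None
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng=None):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        rng = rng or np.random.default_rng()
        self.W = he_uniform(rng, (out_dim, in_dim), in_dim)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.weight_flags = [True, False]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.grads[0][...] = dy.T @ self._x
        self.grads[1][...] = dy.sum(axis=0)
        dx = dy @ self.W
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only when ``training`` is True and an rng is
    supplied; evaluation-mode forward is the identity."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx
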