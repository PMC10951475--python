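"""Minimal convolutional-network building blocks in NumPy.

The restoration network needs only a handful of operations — 3x3 same-pad
convolution, ReLU, 2x2 max pooling, 2x nearest-neighbour upsampling and
channel concatenation — so they are implemented here directly on NumPy
arrays with explicit backward passes, plus an Adam optimizer.  Convolutions
are lowered to a single GEMM via ``sliding_window_view`` (im2col), which
keeps both passes inside BLAS and fast enough for desk-scale training.

Array layout is (N, C, H, W); single precision by default (double is
available for gradient checking).  All randomness goes through an explicit
``numpy.random.Generator``, so initialization and training are reproducible
bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Upsample2", "Adam", "conv2d_same"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for same-pad conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N, C, H, W, k, k
    n, c, h, w = x.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


def conv2d_same(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None):
    """Stride-1, same-padding cross-correlation.

    x: (N, Cin, H, W); weight: (Cout, Cin, k, k).  Returns the output and
    the im2col patch matrix (reused by the backward pass).
    """
    n, _, h, w = x.shape
    cout, cin, k, _ = weight.shape
    cols = _im2col(x, k)
    out = cols @ weight.reshape(cout, cin * k * k).T
    if bias is not None:
        out += bias
    return out.reshape(n, h, w, cout).transpose(0, 3, 1, 2), cols


class Conv2d:
    """3x3 (or 1x1) same-padding convolution with He-normal init."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(dtype)
        self.bias = np.zeros(cout, dtype=dtype)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._cache = None

    @property
    def params(self):
        return [("weight", self.weight), ("bias", self.bias)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out, cols = conv2d_same(x, self.weight, self.bias)
        self._cache = (x.shape, cols)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        (xshape, cols) = self._cache
        n, cin, h, w = xshape
        cout, _, k, _ = self.weight.shape
        g2 = g.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        self.grad_weight = (g2.T @ cols).reshape(self.weight.shape)
        self.grad_bias = g2.sum(axis=0)
        # dx is a same-pad conv of g with the 180deg-rotated, transposed kernel
        w_rot = self.weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = conv2d_same(g, np.ascontiguousarray(w_rot))
        self._cache = None
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    params = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class MaxPool2:
    """2x2 max pooling; gradient routed to the per-block argmax."""

    def __init__(self):
        self._cache = None

    params = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        (n, c, h, w), idx = self._cache
        gz = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gz, idx[..., None], g[..., None], axis=-1)
        gz = gz.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gz.reshape(n, c, h, w)


class Upsample2:
    """2x nearest-neighbour upsampling; gradient sums each 2x2 block."""

    params = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam optimizer over a list of Conv2d layers."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if isinstance(l, Conv2d)]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [(np.zeros_like(l.weight), np.zeros_like(l.bias)) for l in self.layers]
        self.v = [(np.zeros_like(l.weight), np.zeros_like(l.bias)) for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, layer in enumerate(self.layers):
            for j, (param, grad) in enumerate(
                ((layer.weight, layer.grad_weight), (layer.bias, layer.grad_bias))
            ):
                m = self.m[i][j]
                v = self.v[i][j]
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                param -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
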