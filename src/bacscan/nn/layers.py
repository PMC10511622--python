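"""Minimal CPU layer stack for small convolutional classifiers.

Layers operate on NHWC float arrays and implement explicit forward/backward
passes.  Caches needed for the backward pass are only stored when ``cache=True``
is passed to ``forward``; a frozen prefix of a network can therefore run in
pure inference mode during training, which is where most of the FLOPs of a
partially fine-tuned classifier live.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "LeakyReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Dropout",
    "Sigmoid",
]


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base class; stateless layers only implement forward/backward."""

    trainable = False  # whether the layer's params receive updates

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, cache: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# 3x3 tap offsets in raster order; weight row block k corresponds to the
# input shifted by (di-1, dj-1)
_TAPS = [(di - 1, dj - 1) for di in range(3) for dj in range(3)]


def _overlap(h: int, w: int, oi: int, oj: int):
    """Slices (dst, src) such that dst[p] aligns with src[p + (oi, oj)]."""
    dst = (slice(max(0, -oi), h - max(0, oi)), slice(max(0, -oj), w - max(0, oj)))
    src = (slice(max(0, oi), h + min(0, oi)), slice(max(0, oj), w + min(0, oj)))
    return dst, src


class Conv2d(Layer):
    """3x3 same-padding convolution, stride 1, He-initialised.

    Implemented as nine shifted GEMMs on the contiguous input (one per
    kernel tap) rather than via an im2col buffer: the full patch matrix of a
    large mammogram batch is never materialised, so training memory stays
    close to inference memory and the channel-contiguous layout feeds BLAS
    directly.  The backward cache holds only a reference to the input.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, trainable: bool = True, gain: float = 2.0):
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(gain / (9 * c_in))
        self.w = Param((rng.standard_normal((9 * c_in, c_out)) * std).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self.trainable = trainable
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, cache=False):
        n, h, w, c = x.shape
        x2 = np.ascontiguousarray(x).reshape(-1, c)
        y = np.empty((n, h, w, self.c_out), dtype=x.dtype)
        y[...] = self.b.value
        for k, (oi, oj) in enumerate(_TAPS):
            wk = self.w.value[k * c:(k + 1) * c]
            t = (x2 @ wk).reshape(n, h, w, self.c_out)
            dst, src = _overlap(h, w, oi, oj)
            y[:, dst[0], dst[1], :] += t[:, src[0], src[1], :]
        self._x = x if cache else None
        return y

    def backward(self, dy):
        if self._x is None:
            raise RuntimeError("Conv2d.backward called without a cached forward pass")
        x = self._x
        n, h, w, c = x.shape
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        dx = np.zeros_like(x)
        for k, (oi, oj) in enumerate(_TAPS):
            wk = self.w.value[k * c:(k + 1) * c]
            dst, src = _overlap(h, w, oi, oj)
            if self.trainable:
                xs = np.ascontiguousarray(x[:, src[0], src[1], :]).reshape(-1, c)
                ds = np.ascontiguousarray(dy[:, dst[0], dst[1], :]
                                          ).reshape(-1, self.c_out)
                self.w.grad[k * c:(k + 1) * c] += xs.T @ ds
            u = (dy2 @ wk.T).reshape(n, h, w, c)
            dx[:, src[0], src[1], :] += u[:, dst[0], dst[1], :]
        if self.trainable:
            self.b.grad += dy2.sum(axis=0)
        self._x = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3):
        self.alpha = alpha
        self._pos = None

    def forward(self, x, train=False, cache=False):
        pos = x > 0
        y = np.where(pos, x, self.alpha * x)
        self._pos = pos if cache else None
        return y

    def backward(self, dy):
        return np.where(self._pos, dy, self.alpha * dy)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def __init__(self):
        self._win = None
        self._shape = None

    def forward(self, x, train=False, cache=False):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2d needs even spatial dims, got {h}x{w}")
        win = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = win.max(axis=(2, 4))
        if cache:
            self._win = win
            self._shape = x.shape
            self._y = y
        return y

    def backward(self, dy):
        n, h, w, c = self._shape
        # route gradient to argmax positions; ties (measure zero on continuous
        # data) split the gradient
        mask = self._win == self._y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx = mask * (dy[:, :, None, :, None, :] / counts)
        return dx.reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False, cache=False):
        if cache:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), (n, h, w, c)).copy()


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False, cache=False):
        if cache:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 dtype=np.float32, trainable: bool = True, gain: float = 2.0):
        std = np.sqrt(gain / d_in)
        self.w = Param((rng.standard_normal((d_in, units)) * std).astype(dtype))
        self.b = Param(np.zeros(units, dtype=dtype))
        self.trainable = trainable
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, cache=False):
        self._x = x if cache else None
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        if self.trainable:
            self.w.grad += self._x.T @ dy
            self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True`` and an rng is set."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None
        self._mask = None

    def forward(self, x, train=False, cache=False):
        if not train or self.rate == 0.0 or self.rng is None:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask if cache else None
        return x * mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x, train=False, cache=False):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y if cache else None
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)
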