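"""Minimal CPU layer library for the staining networks.

Single-sample layout ``(C, H, W)``, float32 throughout.  Every layer
implements ``forward(x, train)`` caching what its ``backward(dy)`` needs;
``backward`` *accumulates* into ``Param.grad`` and returns the gradient with
respect to the layer input, so a trainer can run several forward/backward
passes per update step (fake and real discriminator passes, the cycle terms)
before a single optimizer step.

Convolutions use TF-style ``same`` padding: for kernel ``k`` and stride
``s`` on size ``n`` the output has ``ceil(n/s)`` positions and the total
padding ``(out-1)*s + k - n`` is split with the extra pixel on the
bottom/right.  Transposed convolutions are implemented exactly as the
adjoint of the corresponding strided convolution, which keeps the two
consistent (and makes the U-Net decoder the mirror of its encoder).
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "SpatialNorm",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Dropout",
    "Concat",
    "Sequential",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    train: bool = True

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """Return (out, pad_begin, pad_end) for TF-style same padding."""
    out = math.ceil(n / s)
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """(C, Hp, Wp) padded input -> (oh*ow, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::s, ::s]  # (C, oh, ow, k, k)
    cols = win.transpose(1, 2, 0, 3, 4).reshape(oh * ow, -1)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, xp_shape: tuple, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` — scatter-add patches back."""
    c = xp_shape[0]
    dxp = np.zeros(xp_shape, dtype=np.float32)
    d = dcols.reshape(oh, ow, c, k, k).transpose(2, 0, 1, 3, 4)  # (C, oh, ow, k, k)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki : ki + oh * s : s, kj : kj + ow * s : s] += d[:, :, :, ki, kj]
    return dxp


def conv2d_forward(x: np.ndarray, w: np.ndarray, s: int):
    """``x`` (Cin,H,W), ``w`` (Cout,Cin,k,k) -> (y, cols, pads)."""
    cin, h, wdt = x.shape
    cout, _, k, _ = w.shape
    oh, pt, pb = _same_pad(h, k, s)
    ow, pl, pr = _same_pad(wdt, k, s)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr)))
    cols = _im2col(xp, k, s, oh, ow)
    y = cols @ w.reshape(cout, -1).T  # (oh*ow, Cout)
    return y.T.reshape(cout, oh, ow), cols, (pt, pb, pl, pr)


def conv2d_backward_input(dy: np.ndarray, w: np.ndarray, s: int, x_shape: tuple) -> np.ndarray:
    cin, h, wdt = x_shape
    cout, _, k, _ = w.shape
    oh, pt, pb = _same_pad(h, k, s)
    ow, pl, pr = _same_pad(wdt, k, s)
    dcols = dy.reshape(cout, -1).T @ w.reshape(cout, -1)  # (oh*ow, Cin*k*k)
    dxp = _col2im(dcols, (cin, h + pt + pb, wdt + pl + pr), k, s, oh, ow)
    return dxp[:, pt : pt + h, pl : pl + wdt]


def conv2d_backward_weight(cols: np.ndarray, dy: np.ndarray, w_shape: tuple) -> np.ndarray:
    cout = w_shape[0]
    dw = dy.reshape(cout, -1) @ cols  # (Cout, Cin*k*k)
    return dw.reshape(w_shape)


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, bias: bool = True, name: str = "conv"):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        fan_in = cin * k * k
        w = np.random.standard_normal((cout, cin, k, k)) / math.sqrt(fan_in)
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b") if bias else None
        self._cache = None

    def params(self) -> List[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y, cols, _ = conv2d_forward(x, self.w.data, self.stride)
        if self.b is not None:
            y = y + self.b.data[:, None, None]
        self._cache = (x.shape, cols)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        self.w.grad += conv2d_backward_weight(cols, dy, self.w.data.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(1, 2))
        return conv2d_backward_input(dy, self.w.data, self.stride, x_shape)


class ConvTranspose2d(Layer):
    """Fractional-stride convolution: the exact adjoint of ``Conv2d``.

    Maps (Cin, H, W) -> (Cout, s*H, s*W).  The stored weight has the shape of
    the *underlying* forward convolution, (Cin, Cout, k, k), i.e. the conv
    that would map the (larger) output back to the input.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 2, bias: bool = True, name: str = "convT"):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        fan_in = cout * k * k
        w = np.random.standard_normal((cin, cout, k, k)) / math.sqrt(fan_in)
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b") if bias else None
        self._cache = None

    def params(self) -> List[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def _out_shape(self, x_shape: tuple) -> tuple:
        _, h, w = x_shape
        return (self.cout, h * self.stride, w * self.stride)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out_shape = self._out_shape(x.shape)
        y = conv2d_backward_input(x, self.w.data, self.stride, out_shape)
        if self.b is not None:
            y = y + self.b.data[:, None, None]
        self._cache = (x, out_shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, out_shape = self._cache
        # dx: run the underlying conv forward on dy.
        dx, cols, _ = conv2d_forward(dy, self.w.data, self.stride)
        self.w.grad += conv2d_backward_weight(cols, x, self.w.data.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(1, 2))
        return dx


class SpatialNorm(Layer):
    """Per-channel normalization over the spatial dimensions of one sample.

    With the batch size of one used throughout training this is what a batch
    normalization layer computes, and it is identical to instance
    normalization — the two names in the two network families share this
    implementation.
    """

    def __init__(self, c: int, eps: float = 1e-5, name: str = "norm"):
        self.eps = eps
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self._cache = None
        #: treat mean/variance as constants in backward (used by the
        #: receptive-field probe, where the statistics' spatial coupling
        #: would mask the convolutional footprint)
        self.detach_stats = False

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.data[:, None, None] * xhat + self.beta.data[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = xhat.shape[1] * xhat.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.data[:, None, None]
        if self.detach_stats:
            return dxhat * inv
        # standard normalization backward, per channel over spatial dims
        return (
            inv / n
            * (n * dxhat - dxhat.sum(axis=(1, 2), keepdims=True) - xhat * (dxhat * xhat).sum(axis=(1, 2), keepdims=True))
        )


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; draws its mask from a shared Generator for replay."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Concat:
    """Channel concatenation helper with a matching gradient split."""

    @staticmethod
    def forward(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.concatenate([a, b], axis=0)

    @staticmethod
    def backward(dy: np.ndarray, ca: int):
        return dy[:ca], dy[ca:]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy
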