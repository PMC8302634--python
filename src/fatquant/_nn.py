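"""Minimal CNN building blocks in numpy (float32, CPU, manual backprop).

Convolution is im2col + matmul; the transposed convolution reuses the same
three primitives through the adjoint identity (its forward pass is the
gradient-of-input of an ordinary convolution and vice versa).  Only what the
segmentation network needs is implemented: 2-D convolution with stride and
zero padding, ReLU, 2x2 max pooling, strided transposed convolution, and
sigmoid + binary cross-entropy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _out_hw(h: int, w: int, k: int, s: int, p: int) -> tuple[int, int]:
    return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1


def im2col(x: np.ndarray, k: int, s: int, p: int) -> np.ndarray:
    """(B,C,H,W) -> (B*Ho*Wo, C*k*k) patch matrix."""
    b, c, h, w = x.shape
    ho, wo = _out_hw(h, w, k, s, p)
    xp = _pad_hw(x, p)
    v = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(b * ho * wo, c * k * k)


def col2im(dcols: np.ndarray, x_shape, k: int, s: int, p: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patch gradients back to (B,C,H,W)."""
    b, c, h, w = x_shape
    ho, wo = _out_hw(h, w, k, s, p)
    dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    dc = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += dc[:, :, ki, kj]
    return dxp[:, :, p:p + h, p:p + w] if p else dxp


def conv_forward(x, weight, bias, s: int, p: int):
    """y = conv(x, W) + b.  weight: (Co, Ci, k, k).  Returns (y, cols)."""
    co, ci, k, _ = weight.shape
    b, c, h, w = x.shape
    ho, wo = _out_hw(h, w, k, s, p)
    cols = im2col(x, k, s, p)
    y = cols @ weight.reshape(co, -1).T
    if bias is not None:
        y += bias
    return y.reshape(b, ho, wo, co).transpose(0, 3, 1, 2), cols


def conv_grad_weight(cols, dy, weight_shape):
    co = weight_shape[0]
    dym = dy.transpose(0, 2, 3, 1).reshape(-1, co)
    dw = (dym.T @ cols).reshape(weight_shape)
    return dw, dym.sum(axis=0)


def conv_grad_input(dy, weight, x_shape, s: int, p: int):
    co = weight.shape[0]
    dym = dy.transpose(0, 2, 3, 1).reshape(-1, co)
    dcols = dym @ weight.reshape(co, -1)
    return col2im(dcols, x_shape, k=weight.shape[2], s=s, p=p)


class Conv2d:
    """3x3 (or 1x1) convolution with stride/pad; He-normal or zero init."""

    def __init__(self, cin, cout, k=3, s=1, p=None, rng=None, zero_init=False, name=""):
        self.k, self.s = k, s
        self.p = (k // 2) if p is None else p
        self.name = name
        if zero_init:
            self.w = np.zeros((cout, cin, k, k), dtype=F32)
        else:
            std = np.sqrt(2.0 / (cin * k * k))
            self.w = (rng.standard_normal((cout, cin, k, k)) * std).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x):
        y, cols = conv_forward(x, self.w, self.b, self.s, self.p)
        self._cache = (cols, x.shape)
        return y

    def backward(self, dy):
        cols, x_shape = self._cache
        dw, db = conv_grad_weight(cols, dy, self.w.shape)
        self.dw += dw
        self.db += db
        return conv_grad_input(dy, self.w, x_shape, self.s, self.p)

    def params(self):
        return [(f"{self.name}.w", self.w, self.dw), (f"{self.name}.b", self.b, self.db)]


def bilinear_kernel(k: int) -> np.ndarray:
    """The standard bilinear-interpolation kernel used to seed learned upsampling."""
    f = (k + 1) // 2
    c = (2 * f - 1 - f % 2) / (2.0 * f)
    og = np.arange(k)
    fil = (1 - np.abs(og / f - c))
    return (fil[:, None] * fil[None, :]).astype(F32)


class ConvTranspose2d:
    """Learned upsampling; weight (Cin, Cout, k, k), bilinear-seeded on the diagonal."""

    def __init__(self, cin, cout, k, s, p, name=""):
        self.k, self.s, self.p = k, s, p
        self.name = name
        self.w = np.zeros((cin, cout, k, k), dtype=F32)
        fil = bilinear_kernel(k)
        for i in range(min(cin, cout)):
            self.w[i, i] = fil
        self.b = np.zeros(cout, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def out_hw(self, h, w):
        return ((h - 1) * self.s + self.k - 2 * self.p,
                (w - 1) * self.s + self.k - 2 * self.p)

    def forward(self, z):
        b, cin, h, w = z.shape
        ho, wo = self.out_hw(h, w)
        u_shape = (b, self.w.shape[1], ho, wo)
        u = conv_grad_input(z, self.w, u_shape, self.s, self.p)
        u += self.b[None, :, None, None]
        self._cache = (z, u_shape)
        return u

    def backward(self, du):
        z, _ = self._cache
        dz, cols = conv_forward(du, self.w, None, self.s, self.p)
        dw, _ = conv_grad_weight(cols, z, self.w.shape)
        self.dw += dw
        self.db += du.sum(axis=(0, 2, 3))
        return dz

    def params(self):
        return [(f"{self.name}.w", self.w, self.dw), (f"{self.name}.b", self.b, self.db)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2, stride-2 max pooling; input H, W must be even."""

    def forward(self, x):
        b, c, h, w = x.shape
        v = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = np.ascontiguousarray(v).reshape(b, c, h // 2, w // 2, 4)
        self._idx = v.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, c, h, w = self._in_shape
        dv = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dv, self._idx[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dv).reshape(b, c, h, w)

    def params(self):
        return []


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy over all pixels/channels; returns (loss, dlogits)."""
    s = sigmoid(logits)
    eps = 1e-7
    loss = -np.mean(targets * np.log(s + eps) + (1 - targets) * np.log(1 - s + eps))
    dlogits = (s - targets) / targets.size
    return float(loss), dlogits.astype(F32)


class Adam:
    """Adam over a model's named parameters (in-place updates)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = params  # list of (name, value, grad)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (name, val, grad), m, v in zip(self.entries, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad * grad
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for _, _, grad in self.entries:
            grad[...] = 0.0
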