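"""Minimal 3D convolutional-network building blocks in numpy.

Implements exactly the pieces the volumetric pix2pix pair needs — strided
3D convolution and transposed convolution, batch normalization, dropout,
the usual activations, and Adam — with explicit forward/backward passes.
Tensors are ``(C, D, H, W)`` float32 with an implicit batch of one, which
is the training regime used throughout (batch size 1).

Convolutions use stride-tricks patch views plus ``tensordot``; the
transposed convolution is implemented as the exact adjoint of the strided
convolution, so shape algebra (k=4, s=2, p=1 doubles/halves each axis) and
gradients are consistent by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "Dropout",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Adam",
]


def _out_size(n, k, s, p):
    return (n + 2 * p - k) // s + 1


def _patches(xp, k, s, out_shape):
    """Read-only view of all k^3 patches at stride s: (C, Do, Ho, Wo, k, k, k)."""
    c = xp.shape[0]
    do, ho, wo = out_shape
    sc, sd, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(c, do, ho, wo, k, k, k),
        strides=(sc, sd * s, sh * s, sw * s, sd, sh, sw),
        writeable=False,
    )


def conv3d_forward(x, w, stride, pad):
    """y[o] = sum_c w[o, c] * patch_c;  w is (O, C, k, k, k)."""
    k = w.shape[2]
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    out_shape = tuple(_out_size(n, k, stride, pad) for n in x.shape[1:])
    v = _patches(xp, k, stride, out_shape)
    return np.tensordot(w, v, axes=([1, 2, 3, 4], [0, 4, 5, 6]))


def conv3d_grad_w(x, gy, k, stride, pad):
    """Weight gradient of conv3d_forward: returns (O, C, k, k, k)."""
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    v = _patches(xp, k, stride, gy.shape[1:])
    return np.tensordot(gy, v, axes=([1, 2, 3], [1, 2, 3]))


def conv3d_grad_x(gy, w, stride, pad, x_spatial):
    """Input gradient of conv3d_forward (also the ConvT forward primitive)."""
    c = w.shape[1]
    k = w.shape[2]
    do, ho, wo = gy.shape[1:]
    padded = tuple(n + 2 * pad for n in x_spatial)
    gxp = np.zeros((c,) + padded, dtype=gy.dtype)
    t = np.tensordot(w, gy, axes=([0], [0]))  # (C, k, k, k, Do, Ho, Wo)
    s = stride
    for i in range(k):
        for j in range(k):
            for l in range(k):
                gxp[:, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s] += \
                    t[:, i, j, l]
    if pad:
        return gxp[:, pad:pad + x_spatial[0], pad:pad + x_spatial[1],
                   pad:pad + x_spatial[2]]
    return gxp


class Layer:
    """Base: parameter/gradient dicts plus optional persistent buffers."""

    def __init__(self):
        self.params = {}
        self.grads = {}
        self.buffers = {}

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    def __init__(self, c_in, c_out, kernel=4, stride=2, pad=1,
                 init_std=0.02, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad, self.kernel = stride, pad, kernel
        self.params["w"] = rng.normal(
            0.0, init_std, (c_out, c_in, kernel, kernel, kernel)
        ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.zero_grad()

    def forward(self, x, train=False):
        self._x = x
        y = conv3d_forward(x, self.params["w"], self.stride, self.pad)
        return y + self.params["b"][:, None, None, None]

    def backward(self, gy):
        self.grads["w"] += conv3d_grad_w(self._x, gy, self.kernel,
                                         self.stride, self.pad)
        self.grads["b"] += gy.sum(axis=(1, 2, 3))
        return conv3d_grad_x(gy, self.params["w"], self.stride, self.pad,
                             self._x.shape[1:])


class ConvTranspose3d(Layer):
    """Adjoint of the strided convolution; with k=4, s=2, p=1 it doubles
    every spatial axis."""

    def __init__(self, c_in, c_out, kernel=4, stride=2, pad=1,
                 init_std=0.02, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.pad, self.kernel = stride, pad, kernel
        self.params["w"] = rng.normal(
            0.0, init_std, (c_in, c_out, kernel, kernel, kernel)
        ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self.zero_grad()

    def out_spatial(self, in_spatial):
        k, s, p = self.kernel, self.stride, self.pad
        return tuple(s * (n - 1) + k - 2 * p for n in in_spatial)

    def forward(self, x, train=False):
        self._x = x
        y = conv3d_grad_x(x, self.params["w"], self.stride, self.pad,
                          self.out_spatial(x.shape[1:]))
        return y + self.params["b"][:, None, None, None]

    def backward(self, gy):
        self.grads["w"] += conv3d_grad_w(gy, self._x, self.kernel,
                                         self.stride, self.pad)
        self.grads["b"] += gy.sum(axis=(1, 2, 3))
        return conv3d_forward(gy, self.params["w"], self.stride, self.pad)


class BatchNorm3d(Layer):
    """Per-channel normalization over the spatial axes (batch of one),
    with running statistics for inference."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, init_std=0.02,
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = rng.normal(1.0, init_std, channels).astype(
            np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self.buffers["running_var"] = np.ones(channels, dtype=np.float32)
        self.zero_grad()

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = (
                (1 - m) * self.buffers["running_mean"] + m * mu
            ).astype(np.float32)
            self.buffers["running_var"] = (
                (1 - m) * self.buffers["running_var"] + m * var
            ).astype(np.float32)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        self._train = train
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None, None]) * inv[:, None, None, None]
        self._xhat, self._inv = xhat, inv
        return (self.params["gamma"][:, None, None, None] * xhat
                + self.params["beta"][:, None, None, None])

    def backward(self, gy):
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] += (gy * xhat).sum(axis=(1, 2, 3))
        self.grads["beta"] += gy.sum(axis=(1, 2, 3))
        g = self.params["gamma"][:, None, None, None]
        gxhat = gy * g
        if not self._train:
            return gxhat * inv[:, None, None, None]
        n = xhat[0].size
        sum_g = gxhat.sum(axis=(1, 2, 3), keepdims=True)
        sum_gx = (gxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        return (gxhat - sum_g / n - xhat * sum_gx / n) * \
            inv[:, None, None, None]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate=0.5):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=False):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, gy):
        return np.where(self._neg, self.slope * gy, gy)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._neg = x < 0
        return np.where(self._neg, 0.0, x)

    def backward(self, gy):
        return np.where(self._neg, 0.0, gy)


class Tanh(Layer):
    def forward(self, x, train=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr, beta1=0.5, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for l, ms, vs in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                ms[k] = b1 * ms[k] + (1 - b1) * g
                vs[k] = b2 * vs[k] + (1 - b2) * g * g
                mhat = ms[k] / bias1
                vhat = vs[k] / bias2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    p.dtype)
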