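"""Minimal feed-forward neural-network core on numpy.

Implements exactly the layer set the pipeline's trainable stages need
(dense, 3x3 convolution, residual blocks, pixel-shuffle upsampling,
global average pooling) with manual backpropagation and an Adam
optimizer.  Everything is deterministic given a `numpy.random.Generator`
and runs in float32 by default; gradients are exact (checked against
finite differences in the test suite).

The layer update rule for a dense layer is h_out = sigma(W h + b),
evaluated batch-wise as x @ W + b with x of shape (N, d_in).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Tanh",
    "Conv2d",
    "GlobalAvgPool2d",
    "Reshape",
    "PixelShuffle",
    "Residual",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "bce_with_logits",
    "mse_loss",
]


class Layer:
    """Base class: stateless unless it owns parameters."""

    params: list  # numpy arrays, updated in place by the optimizer
    grads: list   # parallel gradient arrays, written in place

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in, d_out, rng, init="he", dtype=np.float32):
        super().__init__()
        if init == "he":
            std = np.sqrt(2.0 / d_in)
        else:  # glorot
            std = np.sqrt(2.0 / (d_in + d_out))
        w = rng.normal(0.0, std, size=(d_in, d_out)).astype(dtype)
        b = np.zeros(d_out, dtype=dtype)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x = None

    def forward(self, x):
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dout):
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ w.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


def _im2col(x, k, stride, pad):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride,
                                  j:j + stride * ow:stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(cols, x_shape, k, stride, pad, oh, ow):
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride,
               j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    """3x3 (or kxk) convolution via im2col; 'same'-style padding by default."""

    def __init__(self, c_in, c_out, rng, k=3, stride=1, pad=1,
                 dtype=np.float32):
        super().__init__()
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(c_out, fan_in)).astype(dtype)
        b = np.zeros(c_out, dtype=dtype)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x):
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        w, b = self.params
        out = np.einsum("ok,nkl->nol", w, cols, optimize=True)
        out += b[None, :, None]
        return out.reshape(x.shape[0], self.c_out, oh, ow)

    def backward(self, dout):
        n = dout.shape[0]
        dflat = dout.reshape(n, self.c_out, -1)
        w, _ = self.params
        self.grads[0][...] = np.einsum("nol,nkl->ok", dflat, self._cols,
                                       optimize=True)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("ok,nol->nkl", w, dflat, optimize=True)
        return _col2im(dcols, self._x_shape, self.k, self.stride, self.pad,
                       self._oh, self._ow)


class GlobalAvgPool2d(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).copy()


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape  # per-sample shape

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class PixelShuffle(Layer):
    """Rearrange (N, C*r^2, H, W) -> (N, C, H*r, W*r); a pure permutation."""

    def __init__(self, r):
        super().__init__()
        self.r = r

    def forward(self, x):
        n, crr, h, w = x.shape
        r = self.r
        c = crr // (r * r)
        self._in_shape = x.shape
        y = x.reshape(n, c, r, r, h, w)
        y = y.transpose(0, 1, 4, 2, 5, 3)
        return y.reshape(n, c, h * r, w * r)

    def backward(self, dout):
        n, c, hr, wr = dout.shape
        r = self.r
        h, w = hr // r, wr // r
        y = dout.reshape(n, c, h, r, w, r)
        y = y.transpose(0, 1, 3, 5, 2, 4)
        return y.reshape(self._in_shape)


class Residual(Layer):
    """y = x + inner(x); inner must preserve shape."""

    def __init__(self, inner):
        super().__init__()
        self.inner = inner

    @property
    def params(self):
        return self.inner.params

    @params.setter
    def params(self, v):  # base-class __init__ compatibility
        pass

    @property
    def grads(self):
        return self.inner.grads

    @grads.setter
    def grads(self, v):
        pass

    def forward(self, x):
        return x + self.inner.forward(x)

    def backward(self, dout):
        return dout + self.inner.backward(dout)


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @params.setter
    def params(self, v):
        pass

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    @grads.setter
    def grads(self, v):
        pass

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, y):
    """Mean cross-entropy; returns (loss, dlogits). y is int class index."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p.astype(logits.dtype)
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def bce_with_logits(logits, target):
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits)."""
    logits = logits.ravel()
    target = np.asarray(target, dtype=logits.dtype).ravel()
    p = 1.0 / (1.0 + np.exp(-logits))
    loss = np.mean(np.logaddexp(0.0, logits) - target * logits)
    dlogits = (p - target) / logits.size
    return float(loss), dlogits.reshape(-1, 1).astype(logits.dtype)


def mse_loss(pred, target):
    diff = pred - target
    return float(np.mean(diff ** 2)), (2.0 / diff.size) * diff
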