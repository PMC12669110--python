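"""Minimal numpy neural-network layers with manual backpropagation.

Implements exactly the operations the convolutional VAE needs: stride-2
convolutions and transposed convolutions (im2col/col2im based), dense
layers, ReLU / LeakyReLU / sigmoid activations, and Adam. Every layer
caches its forward inputs and exposes ``backward`` returning the input
gradient; parameter gradients accumulate on the layer. All gradients are
finite-difference checked in the test suite.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(B, C, Hp, Wp) padded input -> (B, C*k*k, oh*ow) patch matrix."""
    B, C = xp.shape[:2]
    cols = np.empty((B, C, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ]
    return cols.reshape(B, C * k * k, oh * ow)


def _col2im(
    cols: np.ndarray, padded_shape: Tuple[int, ...], k: int, stride: int,
    oh: int, ow: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back."""
    B, C = padded_shape[:2]
    xp = np.zeros(padded_shape, dtype=cols.dtype)
    d = cols.reshape(B, C, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[
                :, :, i : i + stride * oh : stride, j : j + stride * ow : stride
            ] += d[:, :, i, j]
    return xp


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution, square kernel, symmetric zero padding."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * std).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = x.shape
        oh = (H + 2 * p - k) // s + 1
        ow = (W + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, k, s, oh, ow)
        W2 = self.W.reshape(self.W.shape[0], -1)
        y = np.matmul(W2, cols) + self.b[None, :, None]
        self._cache = (cols, x.shape, oh, ow)
        return y.reshape(B, -1, oh, ow)

    def backward(self, dy):
        cols, xshape, oh, ow = self._cache
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = xshape
        cout = self.W.shape[0]
        dyf = dy.reshape(B, cout, oh * ow)
        self.grads[0] += np.einsum("bop,bcp->oc", dyf, cols).reshape(self.W.shape)
        self.grads[1] += dyf.sum(axis=(0, 2))
        W2 = self.W.reshape(cout, -1)
        dcols = np.matmul(W2.T, dyf)
        dxp = _col2im(dcols, (B, C, H + 2 * p, W + 2 * p), k, s, oh, ow)
        return dxp[:, :, p : p + H, p : p + W]


class ConvTranspose2d(Layer):
    """Transposed convolution; with k=4, stride=2, pad=1 it doubles H and W."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k / (stride * stride)))
        self.W = (rng.standard_normal((cin, cout, k, k)) * std).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_size(self, n: int) -> int:
        return (n - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x):
        k, s, p = self.k, self.stride, self.pad
        B, cin, H, W = x.shape
        cout = self.W.shape[1]
        ho, wo = self.out_size(H), self.out_size(W)
        xf = x.reshape(B, cin, H * W)
        W2 = self.W.reshape(cin, -1)  # (cin, cout*k*k)
        cols = np.matmul(W2.T, xf)  # (B, cout*k*k, H*W)
        yp = _col2im(cols, (B, cout, ho + 2 * p, wo + 2 * p), k, s, H, W)
        self._cache = (xf, x.shape, ho, wo)
        return yp[:, :, p : p + ho, p : p + wo] + self.b[None, :, None, None]

    def backward(self, dy):
        xf, xshape, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        B, cin, H, W = xshape
        cout = self.W.shape[1]
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(dyp, k, s, H, W)  # (B, cout*k*k, H*W)
        self.grads[0] += np.einsum("bip,bjp->ij", xf, cols).reshape(self.W.shape)
        self.grads[1] += dy.sum(axis=(0, 2, 3))
        W2 = self.W.reshape(cin, -1)
        dx = np.matmul(W2, cols)
        return dx.reshape(xshape)


class Dense(Layer):
    def __init__(self, nin, nout, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / nin)
        self.W = (rng.standard_normal((nin, nout)) * std).astype(dtype)
        self.b = np.zeros(nout, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Reshape(Layer):
    def __init__(self, shape: Sequence[int]):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Flatten(Reshape):
    def __init__(self):
        super().__init__((-1,))


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params, grads, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            if self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
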