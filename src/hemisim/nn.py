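"""Minimal numpy neural-network primitives with explicit backward passes.

Convolution (stride 1, "same" padding) is implemented via im2col so the
heavy lifting is a single matmul per layer; every primitive returns a cache
consumed by its backward function.  Gradients are exercised against central
finite differences in the test suite.

Shapes: feature maps are (B, C, H, W); dense activations are (B, D).
Convolution weights are stored as (C*k*k, F) matrices plus a (F,) bias.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def glorot_init(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches under same-padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    b, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * k * k)


def col2im(cols: np.ndarray, x_shape, k: int) -> np.ndarray:
    """Adjoint of im2col: scatter-add patch gradients back to the input."""
    b, c, h, w = x_shape
    pad = k // 2
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(b, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + h, dj : dj + w] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d_forward(x: np.ndarray, w: np.ndarray, k: int):
    """Same-padded stride-1 convolution; ``w`` is (C*k*k, F).  No bias here so
    that several input branches can be summed before a shared bias."""
    b, c, h, width = x.shape
    cols = im2col(x, k)
    out = cols @ w  # (B, H*W, F)
    y = out.transpose(0, 2, 1).reshape(b, w.shape[1], h, width)
    return y, (cols, x.shape, w, k)


def conv2d_backward(gy: np.ndarray, cache):
    cols, x_shape, w, k = cache
    b, f, h, width = gy.shape
    g = gy.reshape(b, f, h * width).transpose(0, 2, 1)  # (B, H*W, F)
    gw = np.einsum("bpc,bpf->cf", cols, g)
    gcols = g @ w.T
    gx = col2im(gcols, x_shape, k)
    return gx, gw


def maxpool2x2_forward(x: np.ndarray):
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    arg = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return y, (arg, x.shape)


def maxpool2x2_backward(gy: np.ndarray, cache):
    arg, x_shape = cache
    b, c, h, w = x_shape
    gxr = np.zeros((b, c, h // 2, w // 2, 4))
    np.put_along_axis(gxr, arg[..., None], gy[..., None], axis=-1)
    gx = gxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
    return gx


def relu_forward(x):
    y = np.maximum(x, 0.0)
    return y, (x > 0.0)


def relu_backward(gy, mask):
    return gy * mask


def sigmoid_forward(x):
    y = 1.0 / (1.0 + np.exp(-x))
    return y, y


def sigmoid_backward(gy, y):
    return gy * y * (1.0 - y)


def dense_forward(x, w, b):
    return x @ w + b, (x, w)


def dense_backward(gy, cache):
    x, w = cache
    return gy @ w.T, x.T @ gy, gy.sum(axis=0)


class Adam:
    """Adam optimiser over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class SGD:
    """Plain SGD fallback with the same interface as Adam."""

    def __init__(self, params: dict, lr: float):
        self.lr = lr

    def step(self, params: dict, grads: dict):
        for k, g in grads.items():
            params[k] -= self.lr * g
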