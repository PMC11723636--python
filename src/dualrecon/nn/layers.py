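"""Minimal NumPy layers with hand-written backpropagation.

Only what the reconstruction networks need: bias-free 2-D convolutions (3x3
"same" and 1x1), ReLU, batch normalization, 2x2 max pooling and 2x nearest
upsampling.  Arrays are ``(batch, channels, height, width)`` float32; each
layer caches what its backward pass needs and stores parameter gradients on
itself for the optimizer to consume.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "BatchNorm2d", "MaxPool2", "Upsample2", "ConvBlock"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patches with zero 'same' padding."""
    b, c, h, w = x.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (B, C, H, W, k, k) -> (B, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, c * k * k)


class Conv2d:
    """Bias-free convolution, kernel 3x3 (same padding) or 1x1.

    Weights are initialized from a zero-mean normal distribution with
    standard deviation ``sigma``; there is no bias term.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator, sigma: float = 0.05):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.in_ch, self.out_ch, self.ksize = in_ch, out_ch, ksize
        self.w = rng.normal(0.0, sigma, size=(out_ch, in_ch * ksize * ksize)).astype(np.float32)
        self.dw = np.zeros_like(self.w)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        cols = _im2col(x, self.ksize)
        y = cols @ self.w.T  # (B*H*W, out)
        if training:
            self._cols, self._xshape = cols, x.shape
        return y.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = self._xshape
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.dw[...] = dyr.T @ self._cols
        self._cols = None
        # dx = "transposed" convolution: correlate dy with the flipped kernel
        k = self.ksize
        w4 = self.w.reshape(self.out_ch, self.in_ch, k, k)
        wt = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, self.out_ch * k * k)
        cols = _im2col(dy, k)
        dx = cols @ wt.T
        return dx.reshape(b, h, w, self.in_ch).transpose(0, 3, 1, 2)

    def params(self):
        return [(self.w, self.dw)]

    def set_grads_zero(self):
        self.dw = np.zeros_like(self.w)


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, training: bool = False):
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class BatchNorm2d:
    """Per-channel batch normalization with trainable scale and shift.

    Running statistics (exponential moving average, momentum 0.9) are used in
    inference mode, so inference is deterministic and batch-size independent.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = np.ones(n_ch, dtype=np.float32)
        self.beta = np.zeros(n_ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(n_ch, dtype=np.float32)
        self.run_var = np.ones(n_ch, dtype=np.float32)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def forward(self, x, training: bool = False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = np.sum(dy * xhat, axis=(0, 2, 3))
        self.dbeta[...] = np.sum(dy, axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dxhat = dy
        mean_dxhat = dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
        return g * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache = None

    def forward(self, x, training: bool = False):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(h, w)}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (b, c, h, w) = self._cache
        self._cache = None
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h, w)

    def params(self):
        return []


class Upsample2:
    """2x nearest-neighbor upsampling."""

    def forward(self, x, training: bool = False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []


class ConvBlock:
    """3x3 convolution followed by ReLU then batch normalization."""

    def __init__(self, in_ch, out_ch, rng, sigma=0.05):
        self.conv = Conv2d(in_ch, out_ch, 3, rng, sigma)
        self.relu = ReLU()
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x, training: bool = False):
        return self.bn.forward(self.relu.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy):
        return self.conv.backward(self.relu.backward(self.bn.backward(dy)))

    def params(self):
        return self.conv.params() + self.bn.params()
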