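"""Minimal CPU neural-network engine (float32, numpy).

Implements exactly the layers the residual image classifier needs —
same-padded convolution via im2col/col2im, batch normalization, ReLU,
global average pooling, a fully-connected layer and a fused softmax
cross-entropy — each with an explicit backward pass, plus plain SGD with
decoupled L2 weight decay.  Convolutions are expressed as one matrix
multiply per batch so the hot path lives in BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "GlobalAvgPool", "Linear",
           "SoftmaxCrossEntropy", "Sequential", "sgd_step"]

_F32 = np.float32


def _im2col(xp: np.ndarray, k: int, stride: int, hout: int, wout: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, hout, wout), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + hout * stride:stride,
                                  j:j + wout * stride:stride]
    return cols.reshape(n, c * k * k, hout * wout)


def _col2im(dcols: np.ndarray, xp_shape: tuple, k: int, stride: int,
            hout: int, wout: int) -> np.ndarray:
    n, c = xp_shape[:2]
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    dc = dcols.reshape(n, c, k, k, hout, wout)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + hout * stride:stride,
                j:j + wout * stride:stride] += dc[:, :, i, j]
    return dxp


class Conv2d:
    """Same-padded 2-D convolution, no bias (batch norm follows).

    Weight shape (out_channels, in_channels, k, k), He-normal initialized.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (in_channels * kernel * kernel))
        self.weight = rng.normal(0, std, (out_channels, in_channels,
                                          kernel, kernel)).astype(_F32)
        self.grad_weight = np.zeros_like(self.weight)
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2

    @property
    def decayed_params(self):
        return [(self.weight, self.grad_weight)]

    params = decayed_params

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        hout = (h + 2 * p - k) // s + 1
        wout = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s, hout, wout)
        wm = self.weight.reshape(self.weight.shape[0], -1)
        out = np.matmul(wm, cols)          # (N, Cout, L)
        self._cache = (cols, xp.shape, hout, wout)
        return out.reshape(n, -1, hout, wout)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, xp_shape, hout, wout = self._cache
        n = grad_out.shape[0]
        g = grad_out.reshape(n, grad_out.shape[1], -1)
        wm = self.weight.reshape(self.weight.shape[0], -1)
        self.grad_weight[...] = np.einsum(
            "ncl,nkl->ck", g, cols, optimize=True).reshape(self.weight.shape)
        dcols = np.matmul(wm.T, g)
        dxp = _col2im(dcols, xp_shape, self.kernel, self.stride, hout, wout)
        p = self.pad
        self._cache = None
        return dxp[:, :, p:dxp.shape[2] - p, p:dxp.shape[3] - p] if p else dxp


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.grad_gamma = np.zeros_like(self.gamma)
        self.grad_beta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.eps, self.momentum = eps, momentum

    @property
    def params(self):
        return [(self.gamma, self.grad_gamma), (self.beta, self.grad_beta)]

    decayed_params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.grad_gamma[...] = np.sum(grad_out * xhat, axis=(0, 2, 3))
        self.grad_beta[...] = np.sum(grad_out, axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        s1 = self.grad_beta[None, :, None, None]
        s2 = self.grad_gamma[None, :, None, None]
        dx = (g * inv[None, :, None, None] / m) * (m * grad_out - s1 - xhat * s2)
        self._cache = None
        return dx.astype(_F32)


class ReLU:
    params: list = []
    decayed_params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        g = grad_out * self._mask
        self._mask = None
        return g


class GlobalAvgPool:
    """(N, C, H, W) → (N, C) spatial mean."""

    params: list = []
    decayed_params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None] / (h * w),
                               self._shape).astype(_F32)


class Linear:
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = rng.uniform(-bound, bound,
                                  (out_features, in_features)).astype(_F32)
        self.bias = np.zeros(out_features, dtype=_F32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)

    @property
    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    @property
    def decayed_params(self):
        return [(self.weight, self.grad_weight)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grad_weight[...] = grad_out.T @ self._x
        self.grad_bias[...] = grad_out.sum(axis=0)
        g = grad_out @ self.weight
        self._x = None
        return g


class SoftmaxCrossEntropy:
    """Numerically fused softmax + mean cross-entropy over the batch."""

    def forward(self, logits: np.ndarray, target_idx: np.ndarray) -> float:
        z = logits - logits.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
        logp = z - logsumexp
        self._probs = np.exp(logp)
        self._target = target_idx
        return float(-logp[np.arange(len(target_idx)), target_idx].mean())

    def backward(self) -> np.ndarray:
        n = len(self._target)
        g = self._probs.copy()
        g[np.arange(n), self._target] -= 1.0
        return (g / n).astype(_F32)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def decayed_params(self):
        return [p for layer in self.layers for p in layer.decayed_params]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def sgd_step(params, decayed, lr: float, weight_decay: float = 0.0,
             momentum: float = 0.0, velocities: dict | None = None) -> None:
    """In-place SGD update ``w ← w − lr (∇w + λ·w [decayed only])``.

    Plain SGD by default; optional classical momentum keeps one velocity
    buffer per parameter (keyed by id) in ``velocities``.
    """
    decayed_ids = {id(w) for w, _ in decayed}
    for w, g in params:
        step = g + weight_decay * w if id(w) in decayed_ids else g
        if momentum > 0.0 and velocities is not None:
            v = velocities.setdefault(id(w), np.zeros_like(w))
            v *= momentum
            v += step
            step = v
        w -= (lr * step).astype(w.dtype)
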