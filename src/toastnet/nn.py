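"""Minimal 1-D network layers with hand-written backward passes.

Everything operates on arrays shaped ``(batch, length, channels)`` for the
temporal layers and ``(batch, features)`` for the dense head. Each layer
caches what its backward pass needs; ``backward`` must be called with the
gradient of the loss with respect to the layer's output immediately after
the corresponding ``forward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class CausalConv1D:
    """1-D convolution with left-only (causal) padding.

    The input is padded with ``kernel - 1`` zeros on the left, so output
    position ``i`` depends only on input positions ``<= i * stride``.
    Output length is ``ceil(length / stride)``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator) -> None:
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be positive")
        self.kernel, self.stride = kernel, stride
        scale = np.sqrt(2.0 / (kernel * in_channels))
        self.W = rng.normal(0.0, scale, size=(kernel, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        if L < 1:
            raise ValueError("sequence length must be positive")
        k = self.kernel
        xp = np.pad(x, ((0, 0), (k - 1, 0), (0, 0)))
        # windows[b, s, c, t] = xp[b, s + t, c]; window s ends at input s
        windows = sliding_window_view(xp, k, axis=1)
        starts = np.arange(0, L, self.stride)
        win = windows[:, starts]  # (B, out_len, C, k)
        y = np.einsum("bsck,kco->bso", win, self.W) + self.b
        self._cache = (win, starts, (B, L, C))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win, starts, (B, L, C) = self._cache
        self.dW = np.einsum("bsck,bso->kco", win, dy)
        self.db = dy.sum(axis=(0, 1))
        k = self.kernel
        dxp = np.zeros((B, L + k - 1, C))
        for t in range(k):
            # distinct start positions -> plain fancy-index accumulate is safe
            dxp[:, starts + t, :] += np.einsum("bso,co->bsc", dy, self.W[t])
        return dxp[:, k - 1 :, :]


class ReLU:
    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1D:
    """Temporal max pooling without padding: out_len = floor((L-w)/s) + 1."""

    params: list[np.ndarray] = []

    def __init__(self, window: int, stride: int) -> None:
        if window < 1 or stride < 1:
            raise ValueError("window and stride must be positive")
        self.window, self.stride = window, stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        if L < self.window:
            raise ValueError(f"sequence length {L} shorter than pool window")
        starts = np.arange(0, L - self.window + 1, self.stride)
        win = sliding_window_view(x, self.window, axis=1)[:, starts]  # (B,S,C,w)
        amax = win.argmax(axis=3)
        self._cache = (starts, amax, (B, L, C))
        return win.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        starts, amax, (B, L, C) = self._cache
        dx = np.zeros((B, L, C))
        S = len(starts)
        b_idx = np.repeat(np.arange(B), S * C)
        s_idx = np.tile(np.repeat(starts, C), B)
        c_idx = np.tile(np.arange(C), B * S)
        np.add.at(dx, (b_idx, s_idx + amax.ravel(), c_idx), dy.ravel())
        return dx


class Downsample:
    """Keep every ``stride``-th position (positions 0, s, 2s, ...)."""

    params: list[np.ndarray] = []

    def __init__(self, stride: int) -> None:
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x[:, :: self.stride, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, :: self.stride, :] = dy
        return dx


class GlobalAvgPool:
    """Mean over the temporal axis: (B, L, C) -> (B, C)."""

    params: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Dense:
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, scale, size=(in_features, out_features))
        self.b = np.zeros(out_features)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(P: np.ndarray, dP: np.ndarray) -> np.ndarray:
    """Chain dL/dP through the softmax to dL/dlogits."""
    inner = (dP * P).sum(axis=-1, keepdims=True)
    return P * (dP - inner)


class Adam:
    """Adaptive-moment optimizer at the conventional defaults."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
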