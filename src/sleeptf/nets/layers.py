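"""Feedforward layers (conv, pool, dense, dropout) with manual backprop.

Conventions: activations are float32/float64 numpy arrays in NCHW layout
for spatial layers; every layer stores its parameters in ``.params`` and
accumulates gradients in ``.grads`` (same keys) during ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "MaxPool2", "ReLU", "Dense", "Dropout", "softmax", "softmax_xent"]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution via im2col; weight shape (F, C, kh, kw)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 input_grad: bool = True) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.params = {
            "W": _he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
            "b": np.zeros(out_ch, dtype=np.float32),
        }
        self.kernel, self.stride, self.pad = kernel, stride, pad
        # the bottom layer of a network can skip the (expensive) gradient
        # with respect to its input
        self.input_grad = input_grad
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        N, C, H, W = x.shape
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        Ho = (x.shape[2] - k) // s + 1
        Wo = (x.shape[3] - k) // s + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # N,C,Ho,Wo,k,k
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, C * k * k
        )
        Wmat = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = cols @ Wmat.T + self.params["b"]
        out = out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, (N, C, Ho, Wo))
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xpad_shape, (N, C, Ho, Wo) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        F = dout.shape[1]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, F)
        Wmat = self.params["W"].reshape(F, -1)
        self.grads["W"] = (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dmat.sum(axis=0)
        if not self.input_grad:
            return None
        dcols = (dmat @ Wmat).reshape(N, Ho, Wo, C, k, k)
        dxp = np.zeros(xpad_shape, dtype=dout.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u : u + s * Ho : s, v : v + s * Wo : s] += dcols[
                    :, :, :, :, u, v
                ].transpose(0, 3, 1, 2)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; ties split their gradient evenly."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            x = x[:, :, : H - H % 2, : W - W % 2]
            N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
        out = xr.max(axis=(3, 5))
        self._cache = (xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, out = self._cache
        mask = xr == out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True).astype(dout.dtype)
        d = mask * (dout[:, :, :, None, :, None] / counts)
        N, C, Hh, _, Wh, _ = xr.shape
        return d.reshape(N, C, Hh * 2, Wh * 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, (out_dim, in_dim), in_dim),
            "b": np.zeros(out_dim, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
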