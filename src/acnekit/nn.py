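"""Minimal CPU neural-network primitives: conv layers, ReLU, upsampling, Adam.

Layers cache what their backward pass needs, so the usage pattern is one
``forward`` followed by at most one ``backward`` per step.  All weights are
float64 for exact reproducibility; the scale of the networks built here
(tens of thousands of parameters on 64×64 inputs) keeps that affordable.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """B×C×H×W → B×(C·k·k)×(OH·OW) patch matrix."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    cols = np.empty((B, C, k * k, OH, OW), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = x[:, :, i:i + stride * OH:stride,
                                      j:j + stride * OW:stride]
    return cols.reshape(B, C * k * k, OH * OW)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    OH = (Hp - k) // stride + 1
    OW = (Wp - k) // stride + 1
    xpad = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    cols = cols.reshape(B, C, k * k, OH, OW)
    for i in range(k):
        for j in range(k):
            xpad[:, :, i:i + stride * OH:stride, j:j + stride * OW:stride] \
                += cols[:, :, i * k + j]
    return xpad[:, :, pad:pad + H, pad:pad + W] if pad else xpad


class Conv2d:
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: Optional[int] = None, rng: Optional[np.random.Generator] = None,
                 bias_init: float = 0.0):
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in))
        self.w = Param(w)
        self.b = Param(np.full(cout, bias_init, dtype=np.float64))
        self._cache = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        cols = _im2col(x, self.k, self.stride, self.pad)
        y = np.einsum("of,bfp->bop", self.w.data, cols, optimize=True) \
            + self.b.data[None, :, None]
        OH = (x.shape[2] + 2 * self.pad - self.k) // self.stride + 1
        OW = (x.shape[3] + 2 * self.pad - self.k) // self.stride + 1
        self._cache = (cols, x.shape, (OH, OW))
        return y.reshape(B, self.cout, OH, OW)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, x_shape, (OH, OW) = self._cache
        B = gy.shape[0]
        g = gy.reshape(B, self.cout, OH * OW)
        self.w.grad += np.einsum("bop,bfp->of", g, cols, optimize=True)
        self.b.grad += g.sum(axis=(0, 2))
        gcols = np.einsum("of,bop->bfp", self.w.data, g, optimize=True)
        return _col2im(gcols, x_shape, self.k, self.stride, self.pad)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class Upsample2:
    """Nearest-neighbor ×2 spatial upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, C, H, W = gy.shape
        return gy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class Adam:
    def __init__(self, params: List[Param], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
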