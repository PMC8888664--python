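"""Minimal 3D convolutional network engine (numpy, CPU).

Layers operate on single samples shaped ``(channels, D, H, W)`` in
float32.  Convolutions are 3x3x3, stride 1, padding 1 (shape
preserving), implemented by an offset-major im2col (27 contiguous
slice copies, no permuted reshape) + matmul; backward scatters the
column gradient back with 27 shifted adds.  Exactly the pieces the
Fourier-domain QSM network needs — conv, LeakyReLU, dropout, residual
blocks, Adam — nothing more.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

__all__ = ["Conv3d", "LeakyReLU", "Dropout", "ResBlock", "Sequential", "Adam"]

_K = 3  # conv kernel edge; stride 1, pad 1 throughout


class Layer:
    train_mode: bool = False

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode


def _offsets():
    for dz in range(_K):
        for dy in range(_K):
            for dx in range(_K):
                yield dz, dy, dx


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, padding 1, with bias.

    Weights are stored as ``(27 * in_ch, out_ch)`` with the kernel
    offset varying slowest (row ``t * in_ch + c`` holds offset ``t`` of
    input channel ``c``), matching the offset-major column matrix built
    in ``forward``.
    """

    def __init__(self, in_ch: int, out_ch: int):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = np.zeros((_K**3 * in_ch, out_ch), dtype=np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._col: Optional[np.ndarray] = None
        self._shape: Optional[tuple] = None

    def init_random(self, rng: np.random.Generator, gain: float = 1.0) -> None:
        """He-style normal init scaled by ``gain``."""
        sd = gain * np.sqrt(2.0 / self.w.shape[0])
        self.w[:] = rng.normal(0.0, sd, size=self.w.shape).astype(np.float32)
        self.b[:] = 0.0

    def set_center_tap(self, in_ch: int, out_ch: int, value: float) -> None:
        """Add ``value`` at the kernel center for one in->out channel pair
        (used by the identity-preserving initialization)."""
        center = _K**3 // 2
        self.w[center * self.in_ch + in_ch, out_ch] += np.float32(value)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        col = np.empty((_K**3, c, d, h, w), dtype=np.float32)
        for t, (dz, dyy, dxx) in enumerate(_offsets()):
            col[t] = xp[:, dz : dz + d, dyy : dyy + h, dxx : dxx + w]
        col2 = col.reshape(_K**3 * c, d * h * w)
        y = self.w.T @ col2 + self.b[:, None]
        self._col, self._shape = col2, x.shape
        return y.reshape(self.out_ch, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        dyf = dy.reshape(self.out_ch, -1)  # (out_ch, N)
        self.dw[:] = self._col @ dyf.T
        self.db[:] = dyf.sum(axis=1)
        dcol = (self.w @ dyf).reshape(_K**3, c, d, h, w)
        dxp = np.zeros((c, d + 2, h + 2, w + 2), dtype=np.float32)
        for t, (dz, dyy, dxx) in enumerate(_offsets()):
            dxp[:, dz : dz + d, dyy : dyy + h, dxx : dxx + w] += dcol[t]
        self._col = None
        return dxp[:, 1:-1, 1:-1, 1:-1]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = np.float32(slope)
        self._neg: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        neg = x < 0
        self._neg = neg
        return np.where(neg, self.slope * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * dy, dy)


class Dropout(Layer):
    """Inverted elementwise dropout; identity when not in train mode."""

    def __init__(self, rate: float, rng: Optional[np.random.Generator] = None):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.train_mode or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def set_train(self, mode: bool) -> None:
        for l in self.layers:
            l.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class ResBlock(Layer):
    """conv -> LeakyReLU -> dropout -> conv, added back onto the input."""

    def __init__(self, width: int, dropout_rate: float, slope: float,
                 rng: Optional[np.random.Generator] = None,
                 skip_enabled: bool = True):
        self.branch = Sequential([
            Conv3d(width, width),
            LeakyReLU(slope),
            Dropout(dropout_rate, rng),
            Conv3d(width, width),
        ])
        self.skip_enabled = skip_enabled

    def params(self):
        return self.branch.params()

    def grads(self):
        return self.branch.grads()

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        self.branch.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.branch.forward(x)
        return x + y if self.skip_enabled else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.branch.backward(dy)
        return dx + dy if self.skip_enabled else dx


class Adam:
    """Adam with bias correction; operates in-place on layer params."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
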