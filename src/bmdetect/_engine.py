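"""Minimal 3-D CNN engine: conv/ReLU/dropout/max-pool/dense with backprop and Adam.

The classifier family this package trains is small and fixed-shape, so the
engine is deliberately simple and tuned for a single CPU core.  The 3x3x3
same-padded convolution is lowered to 27 accumulating GEMMs over *flat-shifted
row views* of the zero-padded channel-last grid: shifting a voxel offset is a
row offset in the flattened (voxel, channel) matrix, so every GEMM operand is
a zero-copy contiguous slice and BLAS streams at memory speed.  Rows that
wrap across sample boundaries land only in padded-border output positions,
which are never read.  Everything is float32 and deterministic: identical
seeds and data give identical parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg.blas import sgemm

__all__ = ["Conv3D", "ReLU", "Dropout", "MaxPool2", "DenseHead", "Sequential", "Adam"]


def _gemm_acc(c: np.ndarray, a: np.ndarray, b: np.ndarray, beta: float = 1.0) -> None:
    """c = beta*c + a @ b for C-contiguous float32 operands, in place, copy-free.

    Uses the transpose identity (a@b)^T = b^T a^T so every operand is passed
    to BLAS as a Fortran-contiguous view.  ``beta=0`` overwrites ``c`` without
    reading it, so the output buffer needs no zero initialization.
    """
    sgemm(1.0, b.T, a.T, beta=beta, c=c.T, overwrite_c=True)


def _gemm_at_b(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a.T @ b for C-contiguous float32 operands without copies."""
    return sgemm(1.0, a.T, b.T, trans_b=True)


class Conv3D:
    """3x3x3 same-padded convolution, channel-last, weights (27, Cin, Cout).

    ``first=True`` marks the network input layer, whose input gradient is
    never needed and is skipped.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, first: bool = False):
        fan_in = 27 * cin
        self.W = (rng.standard_normal((27, cin, cout)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        # small positive bias keeps narrow layers out of the all-dead ReLU
        # regime during the first optimizer steps
        self.b = np.full(cout, 0.01, dtype=np.float32)
        self.cin, self.cout = cin, cout
        self.first = first
        self._xf = None

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    @staticmethod
    def _offsets(Hp: int, Wp: int) -> list[int]:
        return [
            (dz * Hp + dy) * Wp + dx for dz in range(3) for dy in range(3) for dx in range(3)
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, D, H, W, _ = x.shape
        Dp, Hp, Wp = D + 2, H + 2, W + 2
        xp = np.zeros((B, Dp, Hp, Wp, self.cin), dtype=np.float32)
        xp[:, 1:-1, 1:-1, 1:-1, :] = x
        xf = xp.reshape(-1, self.cin)
        nf = xf.shape[0]
        offsets = self._offsets(Hp, Wp)
        yf = np.empty((nf, self.cout), dtype=np.float32)
        if self.cin == 1:
            m = nf - offsets[-1]
            col = np.empty((m, 27), dtype=np.float32)
            for k, off in enumerate(offsets):
                col[:, k] = xf[off : off + m, 0]
            yf[:m] = col @ self.W.reshape(27, self.cout)
        else:
            for k, off in enumerate(offsets):
                _gemm_acc(yf[: nf - off], xf[off:], self.W[k], beta=0.0 if k == 0 else 1.0)
        self._shape = (B, D, H, W)
        self._xf = xf if train else None
        y = np.ascontiguousarray(yf.reshape(B, Dp, Hp, Wp, self.cout)[:, :D, :H, :W, :])
        y += self.b
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray | None:
        B, D, H, W = self._shape
        Dp, Hp, Wp = D + 2, H + 2, W + 2
        xf = self._xf
        nf = xf.shape[0]
        self.gb = gy.sum(axis=(0, 1, 2, 3)).astype(np.float32)
        gyf = np.zeros((nf, self.cout), dtype=np.float32)
        gyf.reshape(B, Dp, Hp, Wp, self.cout)[:, :D, :H, :W, :] = gy
        offsets = self._offsets(Hp, Wp)
        self.gW = np.empty_like(self.W)
        for k, off in enumerate(offsets):
            self.gW[k] = _gemm_at_b(xf[off:], gyf[: nf - off])
        gx = None
        if not self.first:
            gxf = np.empty_like(xf)
            wt = np.ascontiguousarray(self.W.transpose(0, 2, 1))  # (27, Cout, Cin)
            for k, off in enumerate(offsets):
                _gemm_acc(gxf[off:], gyf[: nf - off], wt[k], beta=0.0 if k == 0 else 1.0)
            gx = np.ascontiguousarray(
                gxf.reshape(B, Dp, Hp, Wp, self.cin)[:, 1:-1, 1:-1, 1:-1, :]
            )
        self._xf = None
        return gx


class ReLU:
    params: list = []
    grads: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x, train=False):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0)

    def backward(self, gy):
        return gy * self._mask


class Dropout:
    """Inverted dropout; identity in inference mode (deterministic forward)."""

    params: list = []
    grads: list = []

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def n_params(self) -> int:
        return 0

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.rate)
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32)
        mask /= keep
        self._mask = mask
        return x * mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class MaxPool2:
    """2x2x2 max-pool.  Gradient is split evenly across tied maxima."""

    params: list = []
    grads: list = []

    def n_params(self) -> int:
        return 0

    def forward(self, x, train=False):
        B, D, H, W, C = x.shape
        xr = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        y = xr.max(axis=(2, 4, 6))
        if train:
            self._x, self._y = x, y
        return y

    def backward(self, gy):
        x, y = self._x, self._y
        B, D, H, W, C = x.shape
        xr = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        yb = y.reshape(B, D // 2, 1, H // 2, 1, W // 2, 1, C)
        mask = (xr == yb).astype(np.float32)
        mask /= mask.sum(axis=(2, 4, 6), keepdims=True)
        gyb = gy.reshape(B, D // 2, 1, H // 2, 1, W // 2, 1, C)
        self._x = self._y = None
        return (mask * gyb).reshape(x.shape)


class DenseHead:
    """Flatten -> single linear unit.  Produces the logit; sigmoid lives in the model."""

    def __init__(self, fan_in: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((fan_in, 1)) * np.sqrt(1.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, train=False):
        self._shape = x.shape
        flat = np.ascontiguousarray(x).reshape(x.shape[0], -1)
        self._flat = flat if train else None
        return (flat @ self.W + self.b)[:, 0]

    def backward(self, gz):
        gz = np.ascontiguousarray(gz[:, None], dtype=np.float32)
        self.gW = _gemm_at_b(self._flat, gz)
        self.gb = gz.sum(axis=0)
        gx = gz @ self.W.T
        self._flat = None
        return gx.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng


class Adam:
    """Adam with the standard bias correction; state per parameter array.

    ``clip_norm`` rescales the global gradient norm before the update, which
    tames the large, highly correlated gradients of the first iterations on
    narrow networks (the failure mode is whole layers dying at ReLU zero).
    """

    def __init__(self, params, lr=5e-5, beta1=0.9, beta2=0.999, eps=1e-8,
                 clip_norm: float | None = 10.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(np.square(g))) for g in grads))
            if total > self.clip_norm:
                scale = np.float32(self.clip_norm / total)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = np.asarray(g, dtype=np.float32).reshape(p.shape)
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
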