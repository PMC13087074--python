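"""Minimal convolutional network engine on numpy + numba.

Implements exactly the layers the input-function predictor needs — N-D
convolution (stride 1), 2x max-pooling, ReLU, residual addition, global
average pooling — with explicit backpropagation and an ADAM optimizer.
Convolutions are im2col + BLAS matmul; the patch gather and its
scatter-add adjoint (col2im) are numba-jitted, which is what makes CPU
training of the full model practical.  1-D convolutions ride the same path
with two singleton spatial axes.

Everything is float32 and deterministic for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numba import njit


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = True
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


@njit(fastmath=True, cache=True)
def _im2col_jit(x, kd, kh, kw, cols):  # pragma: no cover - exercised via ConvND
    N, C, Dp, Hp, Wp = x.shape
    Do, Ho, Wo = Dp - kd + 1, Hp - kh + 1, Wp - kw + 1
    for n in range(N):
        for d in range(Do):
            for h in range(Ho):
                for w in range(Wo):
                    r = ((n * Do + d) * Ho + h) * Wo + w
                    col = 0
                    for c in range(C):
                        for i in range(kd):
                            for j in range(kh):
                                for k in range(kw):
                                    cols[r, col] = x[n, c, d + i, h + j, w + k]
                                    col += 1


@njit(fastmath=True, cache=True)
def _col2im_jit(cols, kd, kh, kw, out):  # pragma: no cover - exercised via ConvND
    N, C, Dp, Hp, Wp = out.shape
    Do, Ho, Wo = Dp - kd + 1, Hp - kh + 1, Wp - kw + 1
    for n in range(N):
        for d in range(Do):
            for h in range(Ho):
                for w in range(Wo):
                    r = ((n * Do + d) * Ho + h) * Wo + w
                    col = 0
                    for c in range(C):
                        for i in range(kd):
                            for j in range(kh):
                                for k in range(kw):
                                    out[n, c, d + i, h + j, w + k] += cols[r, col]
                                    col += 1


class ConvND:
    """Stride-1 convolution (cross-correlation) with optional zero padding.

    Accepts 3-D inputs (N, C, D, H, W) or 1-D sequences (N, C, T); the
    latter are processed with two singleton spatial axes.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, ...],
        pad: tuple[int, ...],
        rng: np.random.Generator,
        name: str = "conv",
    ):
        self.c_in, self.c_out = c_in, c_out
        self.nd = len(kernel)
        self.kernel3 = tuple(kernel) + (1,) * (3 - self.nd)
        self.pad3 = tuple(pad) + (0,) * (3 - self.nd)
        fan_in = c_in * int(np.prod(kernel))
        self.W = Param(_he_init(rng, (c_out, fan_in), fan_in), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=np.float32), f"{name}.b")
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _pad(self, x5: np.ndarray) -> np.ndarray:
        if not any(self.pad3):
            return np.ascontiguousarray(x5)
        return np.pad(x5, [(0, 0), (0, 0)] + [(p, p) for p in self.pad3])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        shape_in = x.shape
        x5 = x.reshape(x.shape[: 2 + self.nd] + (1,) * (3 - self.nd))
        xp = self._pad(x5.astype(np.float32, copy=False))
        kd, kh, kw = self.kernel3
        N = xp.shape[0]
        out_sp = tuple(s - k + 1 for s, k in zip(xp.shape[2:], self.kernel3))
        cols = np.empty((N * int(np.prod(out_sp)), self.c_in * kd * kh * kw), np.float32)
        _im2col_jit(xp, kd, kh, kw, cols)
        out = cols @ self.W.value.T + self.b.value
        out = np.moveaxis(out.reshape((N,) + out_sp + (self.c_out,)), -1, 1)
        if train:
            self._cache = (cols, xp.shape, shape_in)
        out = np.ascontiguousarray(out)
        return out.reshape(out.shape[: 2 + self.nd])

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        cols, xp_shape, shape_in = self._cache
        self._cache = None
        d5 = dout.reshape(dout.shape[: 2 + self.nd] + (1,) * (3 - self.nd))
        dout_rows = np.moveaxis(d5, 1, -1).reshape(-1, self.c_out)
        dout_rows = np.ascontiguousarray(dout_rows, dtype=np.float32)
        self.W.grad += dout_rows.T @ cols
        self.b.grad += dout_rows.sum(axis=0)
        if not need_dx:
            return None
        dcols = dout_rows @ self.W.value
        kd, kh, kw = self.kernel3
        dxp = np.zeros(xp_shape, np.float32)
        _col2im_jit(dcols, kd, kh, kw, dxp)
        pd, ph, pw = self.pad3
        dx = dxp[
            :,
            :,
            pd : dxp.shape[2] - pd or None,
            ph : dxp.shape[3] - ph or None,
            pw : dxp.shape[4] - pw or None,
        ]
        return np.ascontiguousarray(dx).reshape(shape_in)


class ReLU:
    params: list[Param] = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool3d:
    """2x2x2 max pooling; ties share the gradient equally (deterministic)."""

    params: list[Param] = []

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(d, h, w)}")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        if train:
            self._cache = (xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xr, out = self._cache
        self._cache = None
        mask = xr == out[:, :, :, None, :, None, :, None]
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = (dout[:, :, :, None, :, None, :, None] / counts) * mask
        n, c = dout.shape[:2]
        return g.reshape(n, c, dout.shape[2] * 2, dout.shape[3] * 2, dout.shape[4] * 2)


class GlobalAvgPool:
    """Mean over all spatial axes: (N, C, *spatial) -> (N, C)."""

    params: list[Param] = []

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape = self._shape
        self._shape = None
        nvox = int(np.prod(shape[2:]))
        g = (dout / nvox).reshape(dout.shape + (1,) * (len(shape) - 2))
        return np.broadcast_to(g.astype(np.float32), shape).copy()


class ResBlock3d:
    """Two 3x3x3 convolutions with a 1x1x1 projection shortcut when widths differ."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str):
        self.conv1 = ConvND(c_in, c_out, (3, 3, 3), (1, 1, 1), rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = ConvND(c_out, c_out, (3, 3, 3), (1, 1, 1), rng, f"{name}.conv2")
        self.proj = (
            ConvND(c_in, c_out, (1, 1, 1), (0, 0, 0), rng, f"{name}.proj")
            if c_in != c_out
            else None
        )
        self.relu2 = ReLU()

    @property
    def params(self) -> list[Param]:
        p = self.conv1.params + self.conv2.params
        if self.proj is not None:
            p += self.proj.params
        return p

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        shortcut = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu2.forward(y + shortcut, train)

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        d = self.relu2.backward(dout)
        dx_main = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(d)), need_dx=need_dx
        )
        if self.proj is not None:
            dx_short = self.proj.backward(d, need_dx=need_dx)
        else:
            dx_short = d if need_dx else None
        if not need_dx:
            return None
        return dx_main + dx_short


class Adam:
    """ADAM with the standard settings beta=(0.9, 0.999), eps=1e-8."""

    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
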