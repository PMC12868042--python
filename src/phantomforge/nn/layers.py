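"""Layer primitives with caching forward passes and analytic backward passes.

All tensors are float64 arrays shaped (C, H, W); batching is not supported
(the translation nets train one patch at a time). Each layer caches what its
backward pass needs; ``backward(dout)`` returns the gradient w.r.t. the input
and accumulates parameter gradients into ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ReflectionPad",
    "InstanceNorm",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "UpsampleBilinear2x",
    "Sequential",
    "Residual",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    __call__ = lambda self, x: self.forward(x)


def _im2col(xp: np.ndarray, k: int, s: int) -> np.ndarray:
    """(C, Hp, Wp) -> (OH, OW, C, k, k) view copied contiguous."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::s, ::s]  # (C, OH, OW, k, k)
    return np.ascontiguousarray(win.transpose(1, 2, 0, 3, 4))


class Conv2d(Layer):
    """2D convolution (cross-correlation) with optional zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.k, self.s, self.p = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out
        # DCGAN-style init: N(0, 0.02)
        self.weight = Param(rng.normal(0.0, 0.02, size=(c_out, c_in, kernel, kernel)))
        self.bias = Param(np.zeros(c_out))
        self._cache = None

    def out_size(self, h: int) -> int:
        return (h + 2 * self.p - self.k) // self.s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
        oh = (xp.shape[1] - k) // s + 1
        ow = (xp.shape[2] - k) // s + 1
        cols = _im2col(xp, k, s).reshape(oh * ow, -1)
        w = self.weight.value.reshape(self.c_out, -1)
        out = cols @ w.T + self.bias.value
        self._cache = (cols, xp.shape, oh, ow)
        return out.reshape(oh, ow, self.c_out).transpose(2, 0, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, oh, ow = self._cache
        k, s, p = self.k, self.s, self.p
        dmat = dout.transpose(1, 2, 0).reshape(oh * ow, self.c_out)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.weight.value.reshape(self.c_out, -1))
        dcols = dcols.reshape(oh, ow, self.c_in, k, k).transpose(2, 0, 1, 3, 4)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, :, i, j]
        if p:
            return dxp[:, p:-p, p:-p]
        return dxp

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


def _reflect_indices(n: int, p: int) -> np.ndarray:
    return np.concatenate([np.arange(p, 0, -1), np.arange(n), np.arange(n - 2, n - 2 - p, -1)])


class ReflectionPad(Layer):
    def __init__(self, pad: int):
        self.p = pad
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        ir = _reflect_indices(x.shape[1], self.p)
        ic = _reflect_indices(x.shape[2], self.p)
        return x[:, ir][:, :, ic]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        ir = _reflect_indices(h, self.p)
        ic = _reflect_indices(w, self.p)
        tmp = np.zeros((c, h, dout.shape[2]))
        np.add.at(tmp, (slice(None), ir), dout)
        dx = np.zeros((c, h, w))
        np.add.at(dx.transpose(0, 2, 1), (slice(None), ic), tmp.transpose(0, 2, 1))
        return dx


class InstanceNorm(Layer):
    """Per-channel spatial normalization without learned affine parameters."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return xhat

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m1 = dout.mean(axis=(1, 2), keepdims=True)
        m2 = (dout * xhat).mean(axis=(1, 2), keepdims=True)
        return inv * (dout - m1 - xhat * m2)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


def _upsample_matrix(n: int) -> np.ndarray:
    """Dense (2n, n) matrix of 2x bilinear upsampling (half-pixel centres)."""
    u = np.zeros((2 * n, n))
    for i in range(n):
        u[2 * i, i] += 0.75
        u[2 * i, max(i - 1, 0)] += 0.25
        u[2 * i + 1, i] += 0.75
        u[2 * i + 1, min(i + 1, n - 1)] += 0.25
    return u


class UpsampleBilinear2x(Layer):
    """Separable 2x bilinear upsampling; backward is the exact adjoint."""

    _matrices: dict[int, np.ndarray] = {}

    @classmethod
    def _mat(cls, n: int) -> np.ndarray:
        if n not in cls._matrices:
            cls._matrices[n] = _upsample_matrix(n)
        return cls._matrices[n]

    def forward(self, x):
        _, h, w = x.shape
        self._hw = (h, w)
        ur, uc = self._mat(h), self._mat(w)
        return np.einsum("ih,chw,jw->cij", ur, x, uc, optimize=True)

    def backward(self, dout):
        h, w = self._hw
        ur, uc = self._mat(h), self._mat(w)
        return np.einsum("ih,cij,jw->chw", ur, dout, uc, optimize=True)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class Residual(Layer):
    """y = x + body(x); the skip adds the incoming gradient unchanged."""

    def __init__(self, body: Sequential):
        self.body = body

    def forward(self, x):
        return x + self.body.forward(x)

    def backward(self, dout):
        return dout + self.body.backward(dout)

    def params(self):
        return self.body.params()
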