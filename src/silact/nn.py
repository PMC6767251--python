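"""Minimal convolutional network layer stack on numpy.

Implements exactly the pieces the sinogram-inpainting GAN needs — strided 4x4
convolutions, transposed convolutions, batch normalisation, (leaky) ReLU,
sigmoid, dropout and Adam — with explicit forward/backward passes. Tensors
are NHWC (channels last, so im2col patches and GEMM operands are contiguous
and the reshape between patch rows and feature maps is free); convolutions
run as im2col + GEMM, and the transposed convolution is the exact adjoint of
the corresponding strided convolution, so its backward pass is a plain
convolution. Parameters default to float32; layers accept a dtype override,
which the finite-difference gradient tests use to check every backward pass
in float64.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import expit

__all__ = [
    "Param", "Layer", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "LeakyReLU", "ReLU", "Sigmoid", "Dropout", "Adam",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col plumbing (NHWC)
# ---------------------------------------------------------------------------

def _out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    """(B, Hp, Wp, C) -> (B*oh*ow, k*k*C) patch matrix."""
    b, _, _, c = xp.shape
    cols = np.empty((b, oh, ow, k, k, c), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, :, ki, kj] = xp[:, ki:ki + s * oh:s, kj:kj + s * ow:s]
    return cols.reshape(b * oh * ow, k * k * c)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, s: int, p: int,
            oh: int, ow: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to the image."""
    b, h, w, c = x_shape
    dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
    dc = dcols.reshape(b, oh, ow, k, k, c)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki:ki + s * oh:s, kj:kj + s * ow:s] += dc[:, :, :, ki, kj]
    if p == 0:
        return dxp
    return dxp[:, p:-p, p:-p]


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

class Conv2d(Layer):
    """Strided 2D convolution; weight (k, k, C_in, C_out), init N(0, 0.02)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, 0.02, (kernel, kernel, c_in, c_out))
        self.W = Param(w.astype(dtype), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, _ = x.shape
        oh = _out_size(h, self.k, self.s, self.p)
        ow = _out_size(w, self.k, self.s, self.p)
        cols = _im2col(_pad(x, self.p), self.k, self.s, oh, ow)
        y = cols @ self.W.value.reshape(-1, self.c_out) + self.b.value
        self._cache = (cols, x.shape, oh, ow)
        return y.reshape(b, oh, ow, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        dyf = dy.reshape(-1, self.c_out)
        self.W.grad += (cols.T @ dyf).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.W.value.reshape(-1, self.c_out).T
        return _col2im(dcols, x_shape, self.k, self.s, self.p, oh, ow)


class ConvTranspose2d(Layer):
    """Strided transposed convolution, the exact adjoint of :class:`Conv2d`.

    Weight layout (C_in, k, k, C_out); output size ``s*(n-1) + k - 2p``
    (exactly doubles the input for k=4, s=2, p=1).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "deconv"):
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.p = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, 0.02, (c_in, kernel, kernel, c_out))
        self.W = Param(w.astype(dtype), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_shape(self, x_shape: tuple) -> tuple:
        b, h, w, _ = x_shape
        return (b,
                self.s * (h - 1) + self.k - 2 * self.p,
                self.s * (w - 1) + self.k - 2 * self.p,
                self.c_out)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y_shape = self.out_shape(x.shape)
        b, h, w, _ = x.shape
        xf = x.reshape(-1, self.c_in)
        dcols = xf @ self.W.value.reshape(self.c_in, -1)
        y = _col2im(dcols, y_shape, self.k, self.s, self.p, h, w)
        y += self.b.value
        self._cache = (xf, x.shape, y_shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xf, x_shape, y_shape = self._cache
        b, h, w, _ = x_shape
        cols_dy = _im2col(_pad(dy, self.p), self.k, self.s, h, w)
        wmat = self.W.value.reshape(self.c_in, -1)
        dx = (cols_dy @ wmat.T).reshape(b, h, w, self.c_in)
        self.W.grad += (xf.T @ cols_dy).reshape(self.W.value.shape)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        return dx


# ---------------------------------------------------------------------------
# Normalisation, activations, dropout
# ---------------------------------------------------------------------------

class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, name: str = "bn"):
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, x_shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        if not train:
            return dy * self.gamma.value * inv_std
        n = x_shape[0] * x_shape[1] * x_shape[2]
        dxhat = dy * self.gamma.value
        term = dxhat - dxhat.mean(axis=(0, 1, 2)) \
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)) / n
        return term * inv_std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._scale = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        # y = x * (1 if x > 0 else slope); keep the factor for the backward
        self._scale = np.where(x > 0, x.dtype.type(1), x.dtype.type(self.slope))
        return x * self._scale

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._scale


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._out = expit(x)
        return self._out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._out * (1.0 - self._out)


class Dropout(Layer):
    """Inverted dropout; doubles as the generator's noise source z."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

@njit(cache=True)
def _adam_update(p, g, m, v, b1, b2, step_scale, vc, eps):  # pragma: no cover
    for i in range(p.size):
        gi = g[i]
        m[i] = b1 * m[i] + (1.0 - b1) * gi
        v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
        p[i] -= step_scale * m[i] / (np.sqrt(v[i] * vc) + eps)


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-3,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            _adam_update(p.value.ravel(), p.grad.ravel(), m.ravel(), v.ravel(),
                         b1, b2, lr / c1, 1.0 / c2, self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
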