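"""Differentiable layers on (H, W, C) float32 tensors.

Each layer caches what its backward pass needs during ``forward`` and
releases it on ``backward``; parameters accumulate gradients in-place and
are updated by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "ReLU", "MaxPool2", "BilinearUp2", "Dropout", "Adam"]


class Param:
    """A trainable array with its gradient and Adam moment buffers."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Conv2d:
    """k x k convolution, stride 1, 'same' zero padding, He-normal init.

    Weights are stored flattened as ``(k*k*cin, cout)`` so forward/backward
    are single matmuls over im2col patches.
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used here")
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = ksize * ksize * cin
        self.W = Param(rng.standard_normal((fan_in, cout)) * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        H, W, C = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        if self.k == 1:
            cols = x.reshape(H * W, C)
        else:
            xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
            cols = np.empty((H, W, 9, C), dtype=np.float32)
            k = 0
            for di in range(3):
                for dj in range(3):
                    cols[:, :, k, :] = xp[di : di + H, dj : dj + W, :]
                    k += 1
            cols = cols.reshape(H * W, 9 * C)
        out = cols @ self.W.value + self.b.value
        self._cache = (cols, (H, W))
        return out.reshape(H, W, self.cout)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols, (H, W) = self._cache
        self._cache = None
        gf = g.reshape(H * W, self.cout).astype(np.float32)
        self.W.grad += cols.T @ gf
        self.b.grad += gf.sum(axis=0)
        gcols = gf @ self.W.value.T
        if self.k == 1:
            return gcols.reshape(H, W, self.cin)
        gcols = gcols.reshape(H, W, 9, self.cin)
        gxp = np.zeros((H + 2, W + 2, self.cin), dtype=np.float32)
        k = 0
        for di in range(3):
            for dj in range(3):
                gxp[di : di + H, dj : dj + W, :] += gcols[:, :, k, :]
                k += 1
        return gxp[1:-1, 1:-1, :]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, g: np.ndarray) -> np.ndarray:
        m, self._mask = self._mask, None
        return np.where(m, g, np.float32(0.0))


class MaxPool2:
    """2x2 max pooling; gradient routed to the argmax (first on ties)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(H, W)}")
        win = x.reshape(H // 2, 2, W // 2, 2, C).transpose(0, 2, 1, 3, 4).reshape(H // 2, W // 2, 4, C)
        idx = win.argmax(axis=2)
        out = np.take_along_axis(win, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (idx, (H, W, C))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        idx, (H, W, C) = self._cache
        self._cache = None
        gw = np.zeros((H // 2, W // 2, 4, C), dtype=np.float32)
        np.put_along_axis(gw, idx[:, :, None, :], g[:, :, None, :], axis=2)
        return gw.reshape(H // 2, W // 2, 2, 2, C).transpose(0, 2, 1, 3, 4).reshape(H, W, C)


def _upsample_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix mapping n_in samples to n_out (x2 here).

    Output coordinate i samples input coordinate (i + 0.5) * n_in / n_out - 0.5
    (the half-pixel-centre convention), clipped at the borders.
    """
    A = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w = np.clip(src - np.floor(src), 0.0, 1.0)
    w[src < 0] = 0.0
    for i in range(n_out):
        A[i, i0[i]] += 1.0 - w[i]
        A[i, i1[i]] += w[i]
    return A


class BilinearUp2:
    """x2 bilinear upsampling as separable matrix products (exact adjoint)."""

    _mats: dict[tuple[int, int], np.ndarray] = {}

    def __init__(self):
        self._shape = None

    def params(self):
        return []

    @classmethod
    def _mat(cls, n_out: int, n_in: int) -> np.ndarray:
        key = (n_out, n_in)
        if key not in cls._mats:
            cls._mats[key] = _upsample_matrix(n_out, n_in)
        return cls._mats[key]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        H, W, C = x.shape
        self._shape = (H, W, C)
        A = self._mat(2 * H, H)
        B = self._mat(2 * W, W)
        t = np.tensordot(A, x, axes=(1, 0))  # (2H, W, C)
        return np.tensordot(t, B, axes=([1], [1])).transpose(0, 2, 1)  # (2H, 2W, C)

    def backward(self, g: np.ndarray) -> np.ndarray:
        H, W, C = self._shape
        self._shape = None
        A = self._mat(2 * H, H)
        B = self._mat(2 * W, W)
        t = np.tensordot(A.T, g, axes=(1, 0))  # (H, 2W, C)
        return np.tensordot(t, B, axes=([1], [0])).transpose(0, 2, 1)


class Dropout:
    """Inverted dropout; active only during training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / np.float32(keep)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        m, self._mask = self._mask, None
        return g * m


class Adam:
    """Adaptive-moment optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
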