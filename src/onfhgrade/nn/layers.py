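"""Differentiable layers on float32 NumPy arrays, channels-last (NHWC).

3x3 convolutions use a shift-accumulate scheme: the padded image is viewed
as a flat (pixels, channels) matrix and each kernel tap contributes one
contiguous-slice GEMM, so no im2col column matrix is ever materialized.
This keeps the arithmetic in large sequential BLAS calls, which is what
makes CPU training on full 256x256 slices practical.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Conv2d:
    """Stride-1 same-padding convolution (k in {1, 3}) with He init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.k = k
        self.cin, self.cout = cin, cout
        fan_in = cin * k * k
        self.W = (rng.standard_normal((k * k, cin, cout)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None  # padded input, cached for dW
        self._shape: tuple[int, ...] | None = None

    # Flat-offset bookkeeping: output pixel p (in padded coordinates) reads
    # input pixel p + off(tap), where off = (i-1)*Wp + (j-1) for tap (i, j).
    def _taps(self, wp: int):
        for t in range(self.k * self.k):
            i, j = divmod(t, self.k)
            yield t, (i - 1) * wp + (j - 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._shape = x.shape
        if self.k == 1:
            self._xp = x
            y = x.reshape(-1, c) @ self.W[0]
            y += self.b
            return y.reshape(n, h, w, self.cout)
        hp, wp = h + 2, w + 2
        xp = np.zeros((n, hp, wp, c), dtype=F32)
        xp[:, 1:-1, 1:-1] = x
        self._xp = xp
        xf = xp.reshape(n, hp * wp, c)
        npx = hp * wp
        y = np.zeros((n, npx, self.cout), dtype=F32)
        for t, off in self._taps(wp):
            lo, hi = max(0, -off), npx - max(0, off)
            y[:, lo:hi] += xf[:, lo + off : hi + off] @ self.W[t]
        y += self.b
        return np.ascontiguousarray(y.reshape(n, hp, wp, self.cout)[:, 1:-1, 1:-1])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        if self.k == 1:
            dyf = dy.reshape(-1, self.cout)
            xf = self._xp.reshape(-1, c)
            self.gW[0] = xf.T @ dyf
            self.gb[...] = dyf.sum(axis=0)
            return (dyf @ self.W[0].T).reshape(n, h, w, c)
        hp, wp = h + 2, w + 2
        npx = hp * wp
        dyp = np.zeros((n, hp, wp, self.cout), dtype=F32)
        dyp[:, 1:-1, 1:-1] = dy
        dyf = dyp.reshape(n, npx, self.cout)
        xf = self._xp.reshape(n, npx, c)
        dxf = np.zeros((n, npx, c), dtype=F32)
        self.gb[...] = dy.sum(axis=(0, 1, 2))
        for t, off in self._taps(wp):
            lo, hi = max(0, -off), npx - max(0, off)
            dys = dyf[:, lo:hi]
            xs = xf[:, lo + off : hi + off]
            self.gW[t] = np.matmul(xs.transpose(0, 2, 1), dys).sum(axis=0)
            dxf[:, lo + off : hi + off] += dys @ self.W[t].T
        return np.ascontiguousarray(dxf.reshape(n, hp, wp, c)[:, 1:-1, 1:-1])

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0))


class MaxPool2:
    """2x2 max pooling; requires even spatial dimensions."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._shape = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = np.ascontiguousarray(r).reshape(n, h // 2, w // 2, c, 4)
        self._idx = r.argmax(axis=-1)
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dr = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.act1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.act2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act2.forward(self.conv2.forward(self.act1.forward(self.conv1.forward(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv1.backward(self.act1.backward(self.conv2.backward(self.act2.backward(dy))))

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return self.conv1.params() + self.conv2.params()


class Adam:
    """Adam with in-place parameter updates over (param, grad) pairs."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.pairs = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
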