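"""Minimal convolutional-network layer with manual backpropagation.

The enhancement networks here are small encoder-decoder CNNs trained on a
single CPU, so this module implements exactly the pieces they need — strided
convolution, its transpose, pointwise nonlinearities, residual blocks and
Adam — on top of numpy matmuls.  Forward passes cache what backward needs;
``backward`` accumulates parameter gradients in-place and returns the
gradient with respect to the input.

Everything is float32 internally for speed; weight init is seeded
``normal(0, 0.02)`` following DCGAN practice, so any network built from a
config plus a seed is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Module", "Conv2d", "ConvTranspose2d", "ReLU", "LeakyReLU",
    "Sigmoid", "Residual", "Sequential", "Adam",
]

DTYPE = np.float32


class Param:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, Hp, Wp) -> contiguous (B*Ho*Wo, C*k*k) patch matrix."""
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back onto the padded grid."""
    b, c, hp, wp = shape
    dxp = np.zeros(shape, dtype=DTYPE)
    d = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += d[:, :, :, :, ki, kj]
    return dxp


class Conv2d(Module):
    """k x k convolution, zero padding ``pad``, stride ``stride``."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 init_std: float = 0.02, bias: bool = True):
        if pad is None:
            pad = k // 2
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, init_std, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, (ho, wo) = _im2col(xp, self.k, self.stride)
        wm = self.w.value.reshape(self.cout, -1)
        y = cols @ wm.T
        if self.b is not None:
            y += self.b.value
        b = x.shape[0]
        self._cache = (cols, xp.shape, b, ho, wo)
        return y.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, b, ho, wo = self._cache
        dym = np.ascontiguousarray(dy.transpose(0, 2, 3, 1), dtype=DTYPE).reshape(-1, self.cout)
        self.w.grad += (dym.T @ cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dym.sum(axis=0)
        dcols = dym @ self.w.value.reshape(self.cout, -1)
        dxp = _col2im(dcols, xp_shape, self.k, self.stride, ho, wo)
        p = self.pad
        return dxp[:, :, p:dxp.shape[2] - p, p:dxp.shape[3] - p] if p else dxp


class ConvTranspose2d(Module):
    """Transposed convolution: the exact adjoint of a strided Conv2d.

    With ``k = 2 * stride`` and ``pad = stride // 2`` the spatial size is
    multiplied by ``stride``.
    """

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 init_std: float = 0.02, bias: bool = True):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        # stored as the weight of the adjoint (forward) conv: (cin, cout, k, k)
        self.w = Param(rng.normal(0.0, init_std, size=(cin, cout, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def out_size(self, h: int) -> int:
        return self.stride * (h - 1) + self.k - 2 * self.pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        b, cin, h, w = x.shape
        h2, w2 = self.out_size(h), self.out_size(w)
        p = self.pad
        # forward of the transpose == backward-data of a Conv2d(cout -> cin)
        xm = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, cin)
        dcols = xm @ self.w.value.reshape(cin, -1)
        yp_shape = (b, self.cout, h2 + 2 * p, w2 + 2 * p)
        yp = _col2im(dcols, yp_shape, self.k, self.stride, h, w)
        y = yp[:, :, p:p + h2, p:p + w2]
        if self.b is not None:
            y = y + self.b.value[None, :, None, None]
        self._cache = (x, (b, h, w), yp_shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, (b, h, w), yp_shape = self._cache
        p = self.pad
        dyp = np.pad(np.asarray(dy, dtype=DTYPE), ((0, 0), (0, 0), (p, p), (p, p))) if p else np.asarray(dy, dtype=DTYPE)
        cols, (ho, wo) = _im2col(dyp, self.k, self.stride)  # ho == h, wo == w
        xm = x.transpose(0, 2, 3, 1).reshape(-1, self.cin)
        self.w.grad += (xm.T @ cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = cols @ self.w.value.reshape(self.cin, -1).T
        return dx.reshape(b, ho, wo, self.cin).transpose(0, 3, 1, 2)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=DTYPE)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Residual(Module):
    """x + conv(relu(conv(x))) — the bottleneck building block."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.body = Sequential([
            Conv2d(channels, channels, 3, rng=rng),
            ReLU(),
            Conv2d(channels, channels, 3, rng=rng),
        ])

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.body.backward(dy)


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with DCGAN-style defaults; state is exportable for checkpoints."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state(self) -> dict:
        return {"t": self.t, "m": [a.copy() for a in self.m], "v": [a.copy() for a in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
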