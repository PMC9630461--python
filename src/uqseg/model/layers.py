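"""Minimal numpy layers with explicit forward/backward passes.

All tensors are NCHW float32.  Each layer caches what its backward pass needs
on ``self``; layers are therefore single-use per step (sequential train loop),
which is all the package requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution with 'same' zero padding (odd k), via im2col."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, name: str):
        assert k % 2 == 1
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.weight = Param(f"{name}.weight", _he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.bias = Param(f"{name}.bias", np.zeros(out_ch, dtype=np.float32))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H, W, k, k) view -> (B*H*W, C*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * self.k * self.k)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.bias.value
        self._cols, self._shape = cols, (b, c, h, w)
        return np.ascontiguousarray(y.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dyf = dy.transpose(0, 2, 3, 1).reshape(b * h * w, self.out_ch)
        self.weight.grad += (dyf.T @ self._cols).reshape(self.weight.value.shape)
        self.bias.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.weight.value.reshape(self.out_ch, -1)).reshape(b, h, w, c, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w]


class DepthwiseConv2d(Layer):
    """Per-channel k x k spatial filter, 'same' zero padding."""

    def __init__(self, channels: int, k: int, rng: np.random.Generator, name: str):
        assert k % 2 == 1
        self.channels, self.k = channels, k
        self.weight = Param(f"{name}.weight", _he_init(rng, (channels, k, k), k * k))
        self.bias = Param(f"{name}.bias", np.zeros(channels, dtype=np.float32))
        self._win: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # B,C,H,W,k,k view
        y = np.einsum("bchwij,cij->bchw", win, self.weight.value, optimize=True)
        y += self.bias.value[None, :, None, None]
        self._win, self._shape = win, x.shape
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        k, p = self.k, self.k // 2
        self.weight.grad += np.einsum("bchwij,bchw->cij", self._win, dy, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        wv = self.weight.value
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + h, kj:kj + w] += dy * wv[None, :, ki, kj, None, None]
        self._win = None
        return dxp[:, :, p:p + h, p:p + w]


class SeparableConv2d(Layer):
    """Depthwise k x k filter followed by a pointwise 1 x 1 convolution."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, name: str):
        self.depthwise = DepthwiseConv2d(in_ch, k, rng, f"{name}.depthwise")
        self.pointwise = Conv2d(in_ch, out_ch, 1, rng, f"{name}.pointwise")

    def params(self) -> list[Param]:
        return self.depthwise.params() + self.pointwise.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.pointwise.forward(self.depthwise.forward(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(self.pointwise.backward(dy))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32, copy=False)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first maximum."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        d4 = np.zeros((b, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(d4, self._idx[..., None], dy[..., None], axis=-1)
        return d4.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


class UpConv2x2(Layer):
    """2x2 transposed convolution with stride 2 (doubles H and W)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, name: str):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Param(f"{name}.weight", _he_init(rng, (in_ch, out_ch, 2, 2), in_ch))
        self.bias = Param(f"{name}.bias", np.zeros(out_ch, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._x = x
        t = np.einsum("bchw,coad->bohawd", x, self.weight.value, optimize=True)
        y = t.reshape(b, self.out_ch, 2 * h, 2 * w)
        y += self.bias.value[None, :, None, None]
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, o, h2, w2 = dy.shape
        h, w = h2 // 2, w2 // 2
        dyr = dy.reshape(b, o, h, 2, w, 2)
        self.weight.grad += np.einsum("bchw,bohawd->coad", self._x, dyr, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = np.einsum("bohawd,coad->bchw", dyr, self.weight.value, optimize=True)
        self._x = None
        return dx.astype(np.float32, copy=False)


class Dropout(Layer):
    """Inverted Bernoulli dropout; identity when inactive (deterministic mode)."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None or self.rate == 0.0:
            self._mask = None
            return x
        keep = (rng.random(x.shape) >= self.rate).astype(np.float32)
        self._mask = keep / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask
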