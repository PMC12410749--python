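"""Minimal numpy tensor layers with hand-written backpropagation.

Just enough machinery for the desk-scale adapter backbone: 2-D convolution
(im2col), ReLU, 2x2 average pooling, nearest-neighbour upsampling, channel
concatenation, softmax, and Adam.  Tensors are NHWC float64 throughout;
everything is deterministic given the init seed.
"""

from __future__ import annotations

import hashlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2D",
    "ReLU",
    "AvgPool2",
    "Upsample2",
    "softmax",
    "softmax_backward",
    "Adam",
    "params_hash",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2D:
    """Same-padding 2-D convolution (kernel 1 or 3), NHWC."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, name: str = ""):
        assert ksize in (1, 3)
        self.ksize = ksize
        scale = np.sqrt(2.0 / (ksize * ksize * cin))  # He init
        self.weight = Param(rng.normal(0.0, scale, (ksize, ksize, cin, cout)), f"{name}.w")
        self.bias = Param(np.zeros(cout), f"{name}.b")
        self._cache: Optional[Tuple] = None

    @property
    def params(self) -> List[Param]:
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.ksize
        if k == 1:
            return x.reshape(n * h * w, c)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # n,h,w,c,k,k
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * h * w, k * k * c
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        cols = self._im2col(x)
        wmat = self.weight.value.reshape(-1, self.weight.value.shape[-1])
        out = cols @ wmat + self.bias.value
        self._cache = (cols, (n, h, w, c))
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, h, w, c) = self._cache
        k = self.ksize
        cout = dout.shape[-1]
        dflat = dout.reshape(-1, cout)
        wmat = self.weight.value.reshape(-1, cout)
        self.weight.grad += (cols.T @ dflat).reshape(self.weight.value.shape)
        self.bias.grad += dflat.sum(axis=0)
        dcols = dflat @ wmat.T
        if k == 1:
            return dcols.reshape(n, h, w, c)
        dcols = dcols.reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2, w + 2, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


class ReLU:
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class AvgPool2:
    """2x2 average pooling, stride 2 (dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        d = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2) / 4.0
        return d


class Upsample2:
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of softmax: dlogits from dL/dprobs."""
    dot = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - dot)


class Adam:
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def params_hash(params: Sequence[Param]) -> str:
    """SHA-256 over the concatenated parameter bytes (order-sensitive)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
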