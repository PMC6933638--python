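"""Minimal feed-forward CNN engine on numpy.

Implements exactly the layers the two classifier architectures need —
valid 2-D and 1-D convolutions, window/global max pooling, dense layers,
ReLU, inverted dropout — with reverse-mode gradients and an Adam
optimizer. Forward passes cache what the backward pass needs; training
mode enables dropout. All randomness (initialization, dropout masks)
flows through explicitly seeded ``numpy.random.Generator`` objects, so a
network built twice from the same seed has identical weights.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv2D(Layer):
    """Valid (no-padding) 2-D convolution, stride 1, input (B, H, W, C)."""

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        k = kh * kw * c_in
        self.W = Param(glorot_uniform(rng, (k, c_out), k, c_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        B, H, Wd, C = x.shape
        if H < self.kh or Wd < self.kw:
            raise ValueError(f"input {H}x{Wd} smaller than kernel {self.kh}x{self.kw}")
        # (B, H', W', C, kh, kw) -> (B, H', W', kh, kw, C)
        win = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        patches = np.ascontiguousarray(np.moveaxis(win, 3, 5))
        self._pshape = patches.shape
        self._pflat = patches.reshape(-1, self.kh * self.kw * self.c_in)
        Hp, Wp = patches.shape[1], patches.shape[2]
        self._in_shape = x.shape
        y = self._pflat @ self.W.value + self.b.value
        return y.reshape(B, Hp, Wp, self.c_out)

    def backward(self, dy):
        B, Hp, Wp, _ = dy.shape
        dflat = dy.reshape(-1, self.c_out)
        self.W.grad += self._pflat.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dpatch = (dflat @ self.W.value.T).reshape(self._pshape)
        dx = np.zeros(self._in_shape)
        for a in range(self.kh):
            for b in range(self.kw):
                dx[:, a : a + Hp, b : b + Wp, :] += dpatch[:, :, :, a, b, :]
        return dx


class MaxPool2D(Layer):
    """Window-2 stride-2 max pooling with floor semantics (trailing row/col dropped)."""

    def __init__(self, window: int = 2):
        self.w = window

    def forward(self, x, train=False):
        B, H, Wd, C = x.shape
        Hp, Wp = H // self.w, Wd // self.w
        if Hp < 1 or Wp < 1:
            raise ValueError(f"input {H}x{Wd} too small for pool window {self.w}")
        self._in_shape = x.shape
        xc = x[:, : Hp * self.w, : Wp * self.w, :]
        blocks = xc.reshape(B, Hp, self.w, Wp, self.w, C)
        blocks = blocks.transpose(0, 1, 3, 2, 4, 5).reshape(B, Hp, Wp, self.w * self.w, C)
        self._idx = blocks.argmax(axis=3)
        self._bshape = blocks.shape
        return np.take_along_axis(blocks, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy):
        B, Hp, Wp, ww, C = self._bshape
        dblocks = np.zeros(self._bshape)
        np.put_along_axis(dblocks, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        d = dblocks.reshape(B, Hp, Wp, self.w, self.w, C).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape)
        dx[:, : Hp * self.w, : Wp * self.w, :] = d.reshape(B, Hp * self.w, Wp * self.w, C)
        return dx


class Conv1D(Layer):
    """Valid 1-D convolution over (B, L, A) with kernel width w spanning all A columns."""

    def __init__(self, width: int, alphabet: int, filters: int, rng: np.random.Generator):
        self.width, self.alphabet, self.filters = width, alphabet, filters
        k = width * alphabet
        self.W = Param(glorot_uniform(rng, (k, filters), k, filters))
        self.b = Param(np.zeros(filters))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        B, L, A = x.shape
        if L < self.width:
            raise ValueError(f"sequence axis {L} shorter than filter width {self.width}")
        win = sliding_window_view(x, self.width, axis=1)  # (B, L', A, w)
        patches = np.ascontiguousarray(np.moveaxis(win, 2, 3))  # (B, L', w, A)
        self._pshape = patches.shape
        self._pflat = patches.reshape(-1, self.width * A)
        self._in_shape = x.shape
        y = self._pflat @ self.W.value + self.b.value
        return y.reshape(B, patches.shape[1], self.filters)

    def backward(self, dy):
        B, Lp, _ = dy.shape
        dflat = dy.reshape(-1, self.filters)
        self.W.grad += self._pflat.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dpatch = (dflat @ self.W.value.T).reshape(self._pshape)  # (B, L', w, A)
        dx = np.zeros(self._in_shape)
        for a in range(self.width):
            dx[:, a : a + Lp, :] += dpatch[:, :, a, :]
        return dx


class GlobalMaxPool1D(Layer):
    """Reduce (B, L', F) to (B, F) by the per-filter maximum."""

    def forward(self, x, train=False):
        self._idx = x.argmax(axis=1)
        self._in_shape = x.shape
        return np.take_along_axis(x, self._idx[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._in_shape)
        np.put_along_axis(dx, self._idx[:, None, :], dy[:, None, :], axis=1)
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    B = logits.shape[0]
    probs = softmax(logits)
    loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-300))
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    return loss, dlogits / B


class Adam:
    def __init__(self, params: list[Param], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def num_parameters(layers_or_net) -> int:
    """Total size of every trainable tensor (the framework-reported count)."""
    return int(sum(p.value.size for p in layers_or_net.params()))
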