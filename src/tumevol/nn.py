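"""Minimal numpy neural-network core used by the VAF-histogram models.

Implements exactly the pieces the multi-task 1D CNN needs -- same-padding
1D convolutions, dense layers, Hardswish, inverted dropout, average pooling,
flatten -- with hand-written backward passes and an Adam optimiser.  Layers
cache their forward inputs; ``backward`` consumes the upstream gradient and
accumulates parameter gradients in-place.  Dropout stays active at prediction
time when requested, which is what Monte Carlo dropout uncertainty relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1d", "Hardswish", "Dropout", "AvgPool1d", "Flatten",
           "Sequential", "Adam", "sigmoid", "softmax", "DTYPE"]

#: single precision throughout -- ample for histogram inputs and halves the
#: cost of the einsum-based convolutions
DTYPE = np.float32


def sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base class: parameterless layers only override forward/backward."""

    params: list  # list of [array, grad] pairs

    def __init__(self):
        self.params = []

    def forward(self, x, train, rng):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def zero_grad(self):
        for p in self.params:
            p[1][...] = 0.0


class Dense(Layer):
    def __init__(self, n_in, n_out, rng):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class Conv1d(Layer):
    """Same-padding 1-D convolution on (batch, channels, length) arrays."""

    def __init__(self, c_in, c_out, kernel, rng):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel width must be odd")
        self.k = kernel
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale,
                            size=(c_out, c_in, kernel)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def _windows(self, x):
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        return np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)

    def forward(self, x, train, rng):
        self._xw = self._windows(x)          # (B, C, L, k)
        return np.einsum("bclk,ock->bol", self._xw, self.W,
                         optimize=True) + self.b[None, :, None]

    def backward(self, dy):
        self.dW += np.einsum("bol,bclk->ock", dy, self._xw, optimize=True)
        self.db += dy.sum(axis=(0, 2))
        # full correlation of dy with the flipped kernel gives dx
        dyw = self._windows(dy)              # (B, O, L, k)
        return np.einsum("bolk,ock->bcl", dyw, self.W[:, :, ::-1],
                         optimize=True)


class Hardswish(Layer):
    """x * relu6(x + 3) / 6 -- cheap smooth activation."""

    def forward(self, x, train, rng):
        self._x = x
        return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0

    def backward(self, dy):
        x = self._x
        g = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
        return dy * g


class Dropout(Layer):
    """Inverted dropout; active whenever ``train`` is True (training and
    Monte Carlo prediction alike)."""

    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        self._mask = ((rng.random(x.shape) >= self.p).astype(x.dtype)
                      / x.dtype.type(1.0 - self.p))
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class AvgPool1d(Layer):
    """Non-overlapping average pooling with window 2 on (B, C, L)."""

    def forward(self, x, train, rng):
        b, c, l = x.shape
        self._shape = x.shape
        return x.reshape(b, c, l // 2, 2).mean(axis=3)

    def backward(self, dy):
        b, c, l = self._shape
        return np.repeat(dy, 2, axis=2) * 0.5


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalAvgPool1d(Layer):
    """Mean over the length axis: (B, C, L) -> (B, C)."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.mean(axis=2)

    def backward(self, dy):
        b, c, l = self._shape
        return np.broadcast_to(dy[:, :, None], self._shape) / l


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    @property
    def all_params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params)
        return out

    def forward(self, x, train, rng):
        for lay in self.layers:
            x = lay.forward(x, train, rng)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def zero_grad(self):
        for lay in self.layers:
            lay.zero_grad()


class Adam:
    """Adam with optional per-parameter-group learning-rate multipliers."""

    def __init__(self, param_groups, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        # param_groups: list of (params, lr_multiplier)
        self.groups = [(list(params), mult) for params, mult in param_groups]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = [[(np.zeros_like(p[0]), np.zeros_like(p[0]))
                       for p in params] for params, _ in self.groups]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (params, mult), st in zip(self.groups, self.state):
            lr = self.lr * mult
            for (p, g), (m, v) in zip(params, st):
                m *= self.b1
                m += (1.0 - self.b1) * g
                v *= self.b2
                v += (1.0 - self.b2) * g * g
                p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
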