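"""Minimal numpy neural-network primitives.

Small, explicit layers with hand-written backprop and an Adam optimizer —
enough to train the MINE statistics network and a desk-scale convolutional
classifier on one CPU. Shapes follow the (N, features) / (N, C, H, W)
conventions. Nothing here is differentiable automatically; every layer
caches what its backward pass needs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Adam",
    "Dense",
    "MLP",
    "Conv2d",
    "relu",
    "elu",
]


class Param:
    """A trainable array with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adam with optional decoupled weight decay (applied to matrices only)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, decay_mask=None):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        # decay_mask[i] False exempts a parameter (biases, norms) from decay
        self.decay_mask = decay_mask or [p.value.ndim > 1 for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, decay in zip(self.params, self.decay_mask):
            g = p.grad
            p.m *= b1
            p.m += (1 - b1) * g
            p.v *= b2
            p.v += (1 - b2) * g * g
            update = (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)
            if self.weight_decay and decay:
                update = update + self.weight_decay * p.value
            p.value -= lr * update


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def he_normal(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def relu(x):
    return np.maximum(x, 0.0)


def elu(x):
    return np.where(x > 0.0, x, np.expm1(np.minimum(x, 0.0)))


_INITS = {"xavier": xavier_uniform, "he": he_normal}


class Dense:
    def __init__(self, rng, n_in, n_out, init="xavier"):
        self.W = Param(_INITS[init](rng, n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, cache=True):
        if cache:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class _Act:
    """Elementwise activation with cached pre-activations."""

    def __init__(self, kind: str):
        self.kind = kind
        self._z = None

    def forward(self, z, cache=True):
        if cache:
            self._z = z
        if self.kind == "relu":
            return relu(z)
        if self.kind == "elu":
            return elu(z)
        raise ValueError(f"unknown activation {self.kind!r}")

    def backward(self, gy):
        z = self._z
        if self.kind == "relu":
            return gy * (z > 0.0)
        # d/dz elu = 1 for z>0, exp(z) for z<=0
        return gy * np.where(z > 0.0, 1.0, np.exp(np.minimum(z, 0.0)))


class MLP:
    """Fully connected network: n_in -> hidden... -> n_out, with optional dropout.

    Dropout (inverted scaling) is active only when `train=True` and a
    generator is supplied; evaluation passes are deterministic.
    """

    def __init__(self, rng, n_in, hidden, n_out=1, activation="elu",
                 init="xavier", dropout=0.0):
        sizes = [n_in, *hidden, n_out]
        self.dense = [Dense(rng, a, b, init=init) for a, b in zip(sizes[:-1], sizes[1:])]
        self.acts = [_Act(activation) for _ in hidden]
        self.dropout = dropout
        self._masks = None

    def params(self):
        return [p for layer in self.dense for p in layer.params()]

    def forward(self, x, train=False, rng=None, cache=None):
        if cache is None:
            cache = train
        use_dropout = train and self.dropout > 0.0 and rng is not None
        self._masks = [] if use_dropout else None
        h = x
        for i, layer in enumerate(self.dense[:-1]):
            h = self.acts[i].forward(layer.forward(h, cache=cache), cache=cache)
            if use_dropout:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                self._masks.append(mask)
                h = h * mask
        return self.dense[-1].forward(h, cache=cache)

    def backward(self, gy):
        g = self.dense[-1].backward(gy)
        for i in range(len(self.acts) - 1, -1, -1):
            if self._masks is not None:
                g = g * self._masks[i]
            g = self.acts[i].backward(g)
            g = self.dense[i].backward(g)
        return g

    def state(self):
        return [p.value.copy() for p in self.params()]

    def load_state(self, state):
        for p, v in zip(self.params(), state):
            p.value[...] = v


def _im2col(x, stride):
    """x: (N, C, H, W) already padded; 3x3 windows -> (N*oh*ow, C*9)."""
    n, c, h, w = x.shape
    oh = (h - 3) // stride + 1
    ow = (w - 3) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N, C, oh, ow, 3, 3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * 9)
    return np.ascontiguousarray(cols), oh, ow


class Conv2d:
    """3x3 convolution, padding 1, configurable stride, He-initialized."""

    def __init__(self, rng, c_in, c_out, stride=1):
        fan_in = c_in * 9
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in = c_in
        self.c_out = c_out
        self.stride = stride
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, cache=True):
        n = x.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols, oh, ow = _im2col(xp, self.stride)
        y = cols @ self.W.value + self.b.value
        if cache:
            self._cache = (cols, xp.shape, oh, ow)
        return y.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, gy):
        cols, xp_shape, oh, ow = self._cache
        n = gy.shape[0]
        gflat = gy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c_out)
        self.W.grad += cols.T @ gflat
        self.b.grad += gflat.sum(axis=0)
        gcols = (gflat @ self.W.value.T).reshape(n, oh, ow, self.c_in, 3, 3)
        gxp = np.zeros(xp_shape)
        s = self.stride
        for ki in range(3):
            for kj in range(3):
                gxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += \
                    gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return gxp[:, :, 1:-1, 1:-1]
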