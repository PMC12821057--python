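"""Minimal differentiable layers for the LVM regressor.

Implements exactly what the estimator needs — dilated 1-D convolutions with
residual connections, fully connected layers, ReLU, inverted dropout, an Adam
optimizer and reverse-mode gradients — on plain numpy arrays.  Every layer
caches what its backward pass needs; ``backward`` consumes the cache, so each
``forward`` supports one ``backward``.  Gradients with respect to the *inputs*
are returned by ``backward`` (needed for saliency), gradients with respect to
parameters accumulate on ``Param.grad``.

Array conventions: waveforms are ``(batch, channels, time)``; scalar features
``(batch, features)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Linear",
    "ReLU",
    "Dropout",
    "Conv1d",
    "GlobalAvgPool",
    "Sequential",
    "TcnBlock",
    "Adam",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_fan_in_uniform(rng, (n_in, n_out), n_in))
        self.b = Param(_fan_in_uniform(rng, (n_out,), n_in))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, gy):
        self.w.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class Conv1d(Layer):
    """Dilated 1-D convolution with zero 'same' padding.

    Padding is symmetric (acausal) by default: the input window is a complete
    beat, not a stream, so the receptive field may look both ways.  With
    ``causal=True`` all padding moves to the left.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator, causal: bool = False):
        fan_in = c_in * kernel_size
        # weight layout (c_out, c_in, k)
        self.w = Param(_fan_in_uniform(rng, (c_out, c_in, kernel_size), fan_in))
        self.b = Param(_fan_in_uniform(rng, (c_out,), fan_in))
        self.k = kernel_size
        self.d = dilation
        span = (kernel_size - 1) * dilation
        if causal:
            self.pl, self.pr = span, 0
        else:
            self.pl, self.pr = span // 2, span - span // 2
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        # x (B, Cin, T) -> (B, Cout, T)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pl, self.pr)))
        self._xp = xp
        T = x.shape[2]
        y = np.broadcast_to(self.b.value[None, :, None],
                            (x.shape[0], self.b.value.shape[0], T)).copy()
        for j in range(self.k):
            off = j * self.d
            # (Cout,Cin) @ (B,Cin,T) -> (B,Cout,T)
            y += np.matmul(self.w.value[:, :, j], xp[:, :, off:off + T])
        return y

    def backward(self, gy):
        xp = self._xp
        T = gy.shape[2]
        self.b.grad += gy.sum(axis=(0, 2))
        gxp = np.zeros_like(xp)
        for j in range(self.k):
            off = j * self.d
            xs = xp[:, :, off:off + T]
            self.w.grad[:, :, j] += np.tensordot(gy, xs, axes=([0, 2], [0, 2]))
            gxp[:, :, off:off + T] += np.matmul(self.w.value[:, :, j].T, gy)
        if self.pr:
            return gxp[:, :, self.pl:-self.pr]
        return gxp[:, :, self.pl:]


class GlobalAvgPool(Layer):
    """(B, C, T) -> (B, C) mean over time."""

    def __init__(self):
        self._T = None

    def forward(self, x, train=False):
        self._T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy):
        return np.repeat(gy[:, :, None], self._T, axis=2) / self._T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, gy):
        for lay in reversed(self.layers):
            gy = lay.backward(gy)
        return gy


class TcnBlock(Layer):
    """Residual block: two dilated convolutions with ReLU + dropout, plus a
    skip path (1x1 convolution when channel counts differ)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 dropout: float, rng: np.random.Generator, causal: bool = False):
        self.conv1 = Conv1d(c_in, c_out, kernel_size, dilation, rng, causal)
        self.relu1 = ReLU()
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel_size, dilation, rng, causal)
        self.relu2 = ReLU()
        self.drop2 = Dropout(dropout, rng)
        self.skip = None
        if c_in != c_out:
            self.skip = Conv1d(c_in, c_out, 1, 1, rng, causal)
        self.out_relu = ReLU()

    def params(self):
        out = (self.conv1.params() + self.conv2.params())
        if self.skip is not None:
            out += self.skip.params()
        return out

    def forward(self, x, train=False):
        h = self.drop1.forward(self.relu1.forward(
            self.conv1.forward(x, train), train), train)
        h = self.drop2.forward(self.relu2.forward(
            self.conv2.forward(h, train), train), train)
        s = x if self.skip is None else self.skip.forward(x, train)
        return self.out_relu.forward(h + s, train)

    def backward(self, gy):
        gy = self.out_relu.backward(gy)
        gh, gs = gy, gy
        gh = self.conv1.backward(self.relu1.backward(self.drop1.backward(
            self.conv2.backward(self.relu2.backward(self.drop2.backward(gh))))))
        if self.skip is not None:
            gs = self.skip.backward(gs)
        return gh + gs


class Adam:
    """Adam with default moment decay (0.9, 0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
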