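"""Neural layers built on the autodiff tensor, with seeded initialization."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: tracks parameters for the optimizer."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return T.add(T.matmul(x, self.weight), self.bias)


class Conv2D(Module):
    """Same-padded stride-1 2-D convolution."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
        method: str = "auto",
    ):
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        fan_out = out_channels * kh * kw
        self.weight = Tensor(
            glorot(rng, (out_channels, in_channels, kh, kw), fan_in, fan_out),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
        self.method = method

    def __call__(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, method=self.method)


class Embedding(Module):
    """Token-index lookup table; row 0 is a frozen all-zero padding row."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        w = (rng.standard_normal((vocab_size, dim)) * 0.1).astype(np.float32)
        w[0] = 0.0
        self.weight = Tensor(w, requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return T.embedding(self.weight, indices, freeze_row0=True)


class LSTMLayer(Module):
    """Single LSTM layer; consumes (B, T, E), returns (B, T, H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = Tensor(glorot(rng, (n_in, 4 * hidden), n_in, hidden), requires_grad=True)
        self.wh = Tensor(glorot(rng, (hidden, 4 * hidden), hidden, hidden), requires_grad=True)
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias at 1: standard remedy
        self.bias = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, Tn, _ = x.data.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        c = Tensor(np.zeros((B, H), dtype=np.float32))
        outs = []
        for t in range(Tn):
            xt = T.reshape(T.narrow(x, 1, t, 1), (B, -1))
            z = T.add(T.add(T.matmul(xt, self.wx), T.matmul(h, self.wh)), self.bias)
            i = T.sigmoid(T.narrow(z, 1, 0, H))
            f = T.sigmoid(T.narrow(z, 1, H, H))
            g = T.tanh(T.narrow(z, 1, 2 * H, H))
            o = T.sigmoid(T.narrow(z, 1, 3 * H, H))
            c = T.add(T.mul(f, c), T.mul(i, g))
            h = T.mul(o, T.tanh(c))
            outs.append(T.reshape(h, (B, 1, H)))
        return T.concat(outs, axis=1)


class GRULayer(Module):
    """Single GRU layer; consumes (B, T, E), returns (B, T, H)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx_rz = Tensor(glorot(rng, (n_in, 2 * hidden), n_in, hidden), requires_grad=True)
        self.wh_rz = Tensor(glorot(rng, (hidden, 2 * hidden), hidden, hidden), requires_grad=True)
        self.b_rz = Tensor(np.zeros(2 * hidden, dtype=np.float32), requires_grad=True)
        self.wx_n = Tensor(glorot(rng, (n_in, hidden), n_in, hidden), requires_grad=True)
        self.wh_n = Tensor(glorot(rng, (hidden, hidden), hidden, hidden), requires_grad=True)
        self.b_n = Tensor(np.zeros(hidden, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, Tn, _ = x.data.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        outs = []
        for t in range(Tn):
            xt = T.reshape(T.narrow(x, 1, t, 1), (B, -1))
            rz = T.sigmoid(
                T.add(T.add(T.matmul(xt, self.wx_rz), T.matmul(h, self.wh_rz)), self.b_rz)
            )
            r = T.narrow(rz, 1, 0, H)
            z = T.narrow(rz, 1, H, H)
            n = T.tanh(
                T.add(
                    T.add(T.matmul(xt, self.wx_n), T.matmul(T.mul(r, h), self.wh_n)),
                    self.b_n,
                )
            )
            # h' = (1 - z) * n + z * h
            h = T.add(T.add(n, T.scale(T.mul(z, n), -1.0)), T.mul(z, h))
            outs.append(T.reshape(h, (B, 1, H)))
        return T.concat(outs, axis=1)


class Adam:
    """Adam optimizer with standard bias correction."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
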