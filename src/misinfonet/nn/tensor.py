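"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the package's neural models need:
broadcast-aware arithmetic, matmul, pointwise nonlinearities, reshape /
concat / narrow, embedding lookup, 2-D same-padded convolution (tap-loop
and FFT execution paths), 2x2 max pooling, inverted dropout, and a numerically
stable binary cross-entropy on logits. Gradients are accumulated by
topological traversal of the recorded graph.

Arrays are kept in float32; the FFT convolution path is mathematically the
cyclic convolution of zero-padded operands, whose adjoints are cyclic
correlations, so forward and backward agree with the direct path to float
tolerance (covered by gradient-check tests).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import fft as sfft


def _as_f32(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=np.float32))


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            # fresh op outputs are adopted without copy; views and foreign
            # dtypes are copied so later += cannot corrupt shared buffers
            if g.dtype != np.float32 or g.base is not None or not g.flags.owndata:
                g = np.array(g, dtype=np.float32)
            self.grad = g
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from 100-step RNNs are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free intermediate grads, op caches and graph edges as soon
                # as they are consumed: keeps peak memory near one layer's
                node.grad = None
                node._backward = None
                node._parents = ()

    # -- helpers ----------------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- arithmetic ------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        ga = _unbroadcast(g, a.data.shape) if a.requires_grad else None
        gb = _unbroadcast(g, b.data.shape) if b.requires_grad else None
        if ga is not None and gb is ga:
            gb = gb.copy()  # never hand one buffer to two parents
        if ga is not None:
            a._accum(ga)
        if gb is not None:
            b._accum(gb)

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def scale(a, c: float) -> Tensor:
    a = _wrap(a)
    c = float(c)

    def backward(g):
        if a.requires_grad:
            a._accum(g * c)

    return _make(a.data * c, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _make(out_data, (a, b), backward)


# -- nonlinearities --------------------------------------------------------


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    s = s.astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accum(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a) -> Tensor:
    a = _wrap(a)
    t = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (1.0 - t * t))

    return _make(t, (a,), backward)


# -- shape surgery ---------------------------------------------------------


def reshape(a, shape: tuple[int, ...]) -> Tensor:
    a = _wrap(a)

    def backward(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)

    def backward(g):
        start = 0
        for t, s in zip(ts, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + s)
                t._accum(g[tuple(sl)])
            start += s

    return _make(out_data, ts, backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis (autodiff-aware)."""
    a = _wrap(a)
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[sl] = g
            a._accum(full)

    return _make(a.data[sl], (a,), backward)


def mean(a) -> Tensor:
    a = _wrap(a)
    n = a.data.size

    def backward(g):
        if a.requires_grad:
            gs = float(np.asarray(g).ravel()[0])
            a._accum(np.full(a.data.shape, gs / n, dtype=np.float32))

    return _make(a.data.mean(), (a,), backward)


def embedding(weight: Tensor, indices: np.ndarray, freeze_row0: bool = True) -> Tensor:
    """Row lookup ``weight[indices]``; gradient scatter-adds into rows.

    With ``freeze_row0`` the padding row 0 receives no gradient (and should
    be kept zero by the caller), so padding stays inert.
    """
    idx = np.asarray(indices)
    out_data = weight.data[idx]

    def backward(g):
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            np.add.at(gw, idx.ravel(), g.reshape(-1, weight.data.shape[1]))
            if freeze_row0:
                gw[0] = 0.0
            weight._accum(gw)

    return _make(out_data, (weight,), backward)


def dropout(a, rate: float, rng: np.random.Generator, training: bool = True) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    a = _wrap(a)
    if not training or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape, dtype=np.float32) < keep).astype(np.float32)
    mask /= np.float32(keep)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(a.data * mask, (a,), backward)


# -- convolution -----------------------------------------------------------


def _same_pads(k: int) -> tuple[int, int]:
    # total padding k-1, split with the extra cell at the end (keras 'same')
    pt = (k - 1) // 2
    return pt, (k - 1) - pt


def _conv_fwd_direct(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tap-loop convolution in NHWC layout: one GEMM per kernel tap."""
    O, C, kh, kw = w.shape
    B, _, H, W = x.shape
    pt, pb = _same_pads(kh)
    pl, pr = _same_pads(kw)
    # channels-last so each tap is a (..., C) @ (C, O) matmul
    xp = np.ascontiguousarray(
        np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr))).transpose(0, 2, 3, 1)
    )
    y = np.zeros((B, H, W, O), dtype=np.float32)
    for u in range(kh):
        for v in range(kw):
            y += xp[:, u : u + H, v : v + W, :] @ w[:, :, u, v].T
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2)), xp


def _conv_bwd_direct(
    g: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    xp: np.ndarray,
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray]:
    O, C, kh, kw = w.shape
    B, _, H, W = x.shape
    pt, _ = _same_pads(kh)
    pl, _ = _same_pads(kw)
    gn = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, O)  # (BHW, O)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp) if need_dx else None
    for u in range(kh):
        for v in range(kw):
            xs = np.ascontiguousarray(xp[:, u : u + H, v : v + W, :]).reshape(-1, C)
            dw[:, :, u, v] = gn.T @ xs
            if need_dx:
                dxp[:, u : u + H, v : v + W, :] += (gn @ w[:, :, u, v]).reshape(
                    B, H, W, C
                )
    if not need_dx:
        return None, dw
    dx = dxp[:, pt : pt + H, pl : pl + W, :].transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx, dtype=np.float32), dw


def _fft_sizes(H: int, W: int, kh: int, kw: int) -> tuple[int, int]:
    return sfft.next_fast_len(H + kh - 1), sfft.next_fast_len(W + kw - 1)


def _cmul_contract(af: np.ndarray, bf: np.ndarray, pattern: str) -> np.ndarray:
    return np.einsum(pattern, af, bf, optimize=True)


def _conv_fwd_fft(
    x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    n1, n2 = _fft_sizes(H, W, kh, kw)
    xf = sfft.rfft2(x, s=(n1, n2))
    wf = sfft.rfft2(w[:, :, ::-1, ::-1], s=(n1, n2))
    yf = _cmul_contract(xf, wf, "bcxy,ocxy->boxy")
    yfull = sfft.irfft2(yf, s=(n1, n2))
    _, pb = _same_pads(kh)
    _, pr = _same_pads(kw)
    y = yfull[:, :, pb : pb + H, pr : pr + W]
    return np.ascontiguousarray(y, dtype=np.float32), xf, wf


def _conv_bwd_fft(
    g: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    xf: np.ndarray,
    wf: np.ndarray,
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray]:
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    n1, n2 = _fft_sizes(H, W, kh, kw)
    _, pb = _same_pads(kh)
    _, pr = _same_pads(kw)
    gemb = np.zeros((g.shape[0], O, n1, n2), dtype=np.float32)
    gemb[:, :, pb : pb + H, pr : pr + W] = g
    gf = sfft.rfft2(gemb, s=(n1, n2))
    # adjoint of cyclic convolution = cyclic correlation (conjugate spectrum)
    dx = None
    if need_dx:
        dx = sfft.irfft2(
            _cmul_contract(gf, np.conj(wf), "boxy,ocxy->bcxy"), s=(n1, n2)
        )[:, :, :H, :W]
        dx = np.ascontiguousarray(dx, dtype=np.float32)
    dwf = sfft.irfft2(
        _cmul_contract(gf, np.conj(xf), "boxy,bcxy->ocxy"), s=(n1, n2)
    )[:, :, :kh, :kw]
    dw = np.ascontiguousarray(dwf[:, :, ::-1, ::-1], dtype=np.float32)
    return dx, dw


#: kernels with at least this many taps run through the FFT path by default
FFT_TAP_THRESHOLD = 10


def conv2d(x, w, b=None, method: str = "auto") -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation, NN style).

    ``x``: (B, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,) or None.
    ``method``: "direct" (tap-loop GEMM), "fft", or "auto" (FFT for large
    kernels).
    """
    x, w = _wrap(x), _wrap(w)
    O, C, kh, kw = w.data.shape
    H, W = x.data.shape[2], x.data.shape[3]
    if kh > H or kw > W:
        raise ValueError(f"kernel ({kh}x{kw}) larger than input plane ({H}x{W})")
    if method == "auto":
        method = "fft" if kh * kw >= FFT_TAP_THRESHOLD else "direct"

    if method == "direct":
        y, xp = _conv_fwd_direct(x.data, w.data)
        cache = (xp,)
    elif method == "fft":
        y, xf, wf = _conv_fwd_fft(x.data, w.data)
        cache = (xf, wf)
    else:
        raise ValueError(f"unknown conv method {method!r}")

    b = _wrap(b) if b is not None else None
    if b is not None:
        y += b.data.reshape(1, O, 1, 1)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if method == "direct":
            dx, dw = _conv_bwd_direct(
                g, x.data, w.data, cache[0], need_dx=x.requires_grad
            )
        else:
            dx, dw = _conv_bwd_fft(
                g, x.data, w.data, cache[0], cache[1], need_dx=x.requires_grad
            )
        if x.requires_grad:
            x._accum(dx)
        if w.requires_grad:
            w._accum(dw)

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def maxpool2d(a, size: int = 2) -> Tensor:
    """Non-overlapping ``size x size`` max pooling; trailing rows/cols dropped."""
    a = _wrap(a)
    B, C, H, W = a.data.shape
    Hc, Wc = (H // size) * size, (W // size) * size
    x = a.data[:, :, :Hc, :Wc]
    xr = x.reshape(B, C, Hc // size, size, Wc // size, size)
    patches = xr.transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Hc // size, Wc // size, size * size
    )
    arg = patches.argmax(axis=-1)
    y = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not a.requires_grad:
            return
        gp = np.zeros_like(patches)
        np.put_along_axis(gp, arg[..., None], g[..., None], axis=-1)
        gx = (
            gp.reshape(B, C, Hc // size, Wc // size, size, size)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, Hc, Wc)
        )
        full = np.zeros_like(a.data)
        full[:, :, :Hc, :Wc] = gx
        a._accum(full)

    return _make(y, (a,), backward)


def bce_with_logits(logits, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    ``loss = mean(softplus(z) - y * z)``; gradient ``(sigmoid(z) - y) / n``.
    """
    z = _wrap(logits)
    y = np.asarray(targets, dtype=np.float64).reshape(z.data.shape)
    zd = z.data.astype(np.float64)
    softplus = np.where(zd > 0, zd + np.log1p(np.exp(-zd)), np.log1p(np.exp(zd)))
    loss = float(np.mean(softplus - y * zd))
    s = 1.0 / (1.0 + np.exp(-zd))

    def backward(g):
        if z.requires_grad:
            gs = float(np.asarray(g).ravel()[0])
            z._accum((gs * (s - y) / y.size).astype(np.float32))

    return _make(np.float32(loss), (z,), backward)
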