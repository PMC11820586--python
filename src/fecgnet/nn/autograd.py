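"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine covering exactly the operations the
W-shaped extraction network needs: 1-D same-padded convolution, 2:1 max
pooling, 2x linear upsampling, pointwise arithmetic, the usual activations,
channel concatenation and full reductions.  Everything is float64 and
single-threaded numpy; determinism follows from seeding the initializers.

Gradients for every primitive are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv1d", "maxpool2", "upsample_linear2"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all parents."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            node._backward = None
            node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    # -- activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), bw)

    def sigmoid(self):
        x = self.data
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bw)

    # -- reductions --------------------------------------------------------
    def mean(self):
        n = self.data.size

        def bw(g):
            self._accum(np.full_like(self.data, float(g) / n))

        return Tensor._make(np.asarray(self.data.mean()), (self,), bw)

    def sum(self):
        def bw(g):
            self._accum(np.full_like(self.data, float(g)))

        return Tensor._make(np.asarray(self.data.sum()), (self,), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` (channel axis by default)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(data, tuple(tensors), bw)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 1-D convolution (cross-correlation).

    x: (B, C_in, L); w: (C_out, C_in, K) with K odd; b: (C_out,) or None.
    Output: (B, C_out, L).
    """
    K = w.data.shape[2]
    if K % 2 == 0:
        raise ValueError("kernel size must be odd for same padding")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, K, axis=2)  # (B, C_in, L, K)
    out = np.einsum("bclk,ock->bol", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("bol,bclk->ock", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (0, 0), (pad, pad)))
            gwin = sliding_window_view(gp, K, axis=2)  # (B, C_out, L, K)
            wf = w.data[:, :, ::-1]
            x._accum(np.einsum("bolk,ock->bcl", gwin, wf, optimize=True))

    return Tensor._make(out, parents, bw)


def maxpool2(x: Tensor) -> Tensor:
    """Max pooling with kernel 2, stride 2 over the last axis."""
    B, C, L = x.data.shape
    if L % 2:
        raise ValueError("length must be even for 2:1 pooling")
    pairs = x.data.reshape(B, C, L // 2, 2)
    arg = pairs.argmax(axis=3)
    out = np.take_along_axis(pairs, arg[..., None], axis=3)[..., 0]

    def bw(g):
        gx = np.zeros_like(pairs)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
        x._accum(gx.reshape(B, C, L))

    return Tensor._make(out, (x,), bw)


def _linear_interp_coeffs(L_out: int, L_in: int):
    """Index pairs and weights for linear interpolation (half-pixel centers)."""
    pos = (np.arange(L_out) + 0.5) * (L_in / L_out) - 0.5
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    i1 = np.clip(i0 + 1, 0, L_in - 1)
    i0 = np.clip(i0, 0, L_in - 1)
    return i0, i1, frac


def upsample_linear2(x: Tensor) -> Tensor:
    """Double the temporal length by linear interpolation."""
    B, C, L = x.data.shape
    i0, i1, frac = _linear_interp_coeffs(2 * L, L)
    out = (1.0 - frac) * x.data[:, :, i0] + frac * x.data[:, :, i1]

    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), i0), g * (1.0 - frac))
        np.add.at(gx, (slice(None), slice(None), i1), g * frac)
        x._accum(gx)

    return Tensor._make(out, (x,), bw)
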