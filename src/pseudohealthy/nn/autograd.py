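"""Compact reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the synthesis networks need: 2-D
convolution (stride/padding/dilation) via im2col, nearest upsampling,
average pooling, pointwise nonlinearities, reductions, concatenation,
spatial flips and a patch-matrix application used by the attention
transfer module.  Tensors are float32, NCHW layout for feature maps.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d"]


def _as_f32(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float32)
    # ascontiguousarray promotes 0-d to 1-d; restore the original shape
    return np.ascontiguousarray(arr).reshape(arr.shape)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._prev: tuple = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------
    @staticmethod
    def _make(data, prev, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in prev))
        if out.requires_grad:
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
        # free graph references so repeated forward passes do not leak
        for node in topo:
            node._prev = ()
            node._backward = None

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor/tensor division not supported; multiply by a constant reciprocal")
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, self._coerce(other)

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bw)

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        a = self
        pos = a.data > 0

        def bw(g):
            a._accum(g * pos)

        return Tensor._make(a.data * pos, (a,), bw)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        factor = np.where(a.data > 0, np.float32(1.0), np.float32(slope))

        def bw(g):
            a._accum(g * factor)

        return Tensor._make(a.data * factor, (a,), bw)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = a.data <= 0
        expm1 = np.expm1(np.minimum(a.data, 0.0)) * alpha
        out = np.where(neg, expm1, a.data)

        def bw(g):
            a._accum(g * np.where(neg, expm1 + alpha, 1.0).astype(np.float32))

        return Tensor._make(out, (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bw)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - t * t))

        return Tensor._make(t, (a,), bw)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def bw(g):
            a._accum(g * sign)

        return Tensor._make(np.abs(a.data), (a,), bw)

    def maximum(self, scalar: float):
        a = self
        keep = a.data > scalar

        def bw(g):
            a._accum(g * keep)

        return Tensor._make(np.maximum(a.data, scalar), (a,), bw)

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float32))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def bw(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    def flip_w(self):
        """Reverse the last (width) axis."""
        a = self

        def bw(g):
            a._accum(g[..., ::-1])

        return Tensor._make(a.data[..., ::-1], (a,), bw)

    def perm_channels(self, perm: np.ndarray):
        """Reorder axis 1 (channels for NCHW / input-channels for OIHW)."""
        a = self
        perm = np.asarray(perm)
        inv = np.argsort(perm)

        def bw(g):
            a._accum(g[:, inv])

        return Tensor._make(a.data[:, perm], (a,), bw)

    # -- spatial ops -----------------------------------------------------
    def upsample2(self):
        """Nearest-neighbour x2 upsampling of an NCHW tensor."""
        a = self
        out = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def bw(g):
            n, c, h, w = a.data.shape
            a._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._make(out, (a,), bw)

    def avg_pool2(self):
        a = self
        n, c, h, w = a.data.shape
        out = a.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def bw(g):
            gg = (g * 0.25)[:, :, :, None, :, None]
            a._accum(np.broadcast_to(gg, (n, c, h // 2, 2, w // 2, 2)).reshape(n, c, h, w).astype(np.float32))

        return Tensor._make(out, (a,), bw)

    def apply_patch_matrix(self, mat: np.ndarray):
        """y[n,p,d] = sum_q mat[p,q] x[n,q,d] with constant `mat`."""
        a = self
        mat = _as_f32(mat)

        def bw(g):
            a._accum(np.einsum("pq,npd->nqd", mat.T, g, optimize=True))

        return Tensor._make(np.einsum("pq,nqd->npd", mat, a.data, optimize=True), (a,), bw)

    def bce_with_logits(self, target: np.ndarray):
        """Mean binary cross-entropy with a numerically stable closed form."""
        a = self
        t = _as_f32(target)
        z = a.data
        loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

        def bw(g):
            a._accum(g * (s - t) / z.size)

        return Tensor._make(loss.mean(), (a,), bw)


# -- convolution ---------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int):
    n, c, h, w = x.shape
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    ho = (h - eh) // stride + 1
    wo = (w - ew) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]  # n,c,ho,wo,kh,kw
    return win, ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation of NCHW `x` with OIHW kernel `w`."""
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    o, ci, kh, kw = w.data.shape
    win, ho, wo = _im2col(xd, kh, kw, stride, dilation)
    out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if w.requires_grad:
            w._accum(np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("nohw,ocij->ncijhw", g, w.data, optimize=True)
            n, c, h, wd = xd.shape
            dxp = np.zeros((n, c, h, wd), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i * dilation:i * dilation + stride * ho:stride,
                        j * dilation:j * dilation + stride * wo:stride] += dcols[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding or None, padding:-padding or None]
            x._accum(dxp)

    return Tensor._make(out, parents, bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)
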