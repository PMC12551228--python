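"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model, its attention scorer and the margin regularizer are differentiable
compositions of a small set of primitives (broadcasting arithmetic, matmul,
2-D convolution, pooling, indexing, reductions and pointwise nonlinearities).
Gradients are accumulated by a topologically ordered backward sweep; every
primitive's gradient is validated against central finite differences in the
test suite.

All computation is float64 numpy, single threaded from the caller's point of
view, so identical seeds give bit-identical results.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "maxpool2d", "log_softmax", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking ndarray <op> Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed gradient: ones)."""
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other) ** (-1.0)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self ** (-1.0)

    def __pow__(self, p: float):
        a = self

        def bw(g):
            a._accum(_unbroadcast(g * p * a.data ** (p - 1.0), a.shape))

        return self._make(a.data**p, (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor.as_tensor(other)
        if a.data.ndim != 2 or b.data.ndim != 2:
            raise ValueError("matmul expects 2-D operands")

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), bw)

    # -- pointwise nonlinearities -------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return self._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        return self**0.5

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return self._make(a.data * mask, (a,), bw)

    def clip_min(self, lo: float):
        """max(x, lo) elementwise; gradient flows where x > lo."""
        a = self
        mask = a.data > lo

        def bw(g):
            a._accum(g * mask)

        return self._make(np.maximum(a.data, lo), (a,), bw)

    # -- reductions / shaping ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy() if np.ndim(g) else np.full(a.shape, g))
            else:
                g_ = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g_, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            a._accum(g.reshape(a.shape))

        return self._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(range(a.ndim))[::-1]
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            np.add.at(a.grad, idx, g)

        return self._make(a.data[idx], (a,), bw)


# -- structural ops ----------------------------------------------------------


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._prev = tuple(tensors)
        out._backward = bw
    return out


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax; the max shift is treated as constant."""
    shift = np.max(logits.data, axis=axis, keepdims=True)
    z = logits - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, L) column view for valid positions."""
    n, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]  # (N, C, Ho, Wo, kh, kw)
    ho, wo = win.shape[2], win.shape[3]
    col = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(col)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (Cout, Cin, kh, kw)."""
    xt, wt = Tensor.as_tensor(x), Tensor.as_tensor(weight)
    n, cin, h, w = xt.shape
    cout, cin_w, kh, kw = wt.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(xt.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xt.data
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    col = _im2col(xp, kh, kw, stride)                       # (N, Ck², L)
    wmat = wt.data.reshape(cout, cin * kh * kw)
    out_data = np.einsum("ok,nkl->nol", wmat, col).reshape(n, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = [xt, wt] + ([bias] if bias is not None else [])

    def bw(g):
        gmat = g.reshape(n, cout, ho * wo)
        if wt.requires_grad:
            gw = np.einsum("nol,nkl->ok", gmat, col).reshape(wt.shape)
            wt._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if xt.requires_grad:
            # col2im: scatter column gradients back onto the padded image
            gcol = np.einsum("ok,nol->nkl", wmat, gmat).reshape(n, cin, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += gcol[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:padding + h, padding:padding + w]
            xt._accum(gxp)

    out = Tensor(out_data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._prev = tuple(parents)
        out._backward = bw
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    xt = Tensor.as_tensor(x)
    stride = stride or kernel
    n, c, h, w = xt.shape
    if padding:
        xp = np.pad(xt.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = xt.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, :, :]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        gxp = np.zeros_like(xp)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        ni, ci, oi, oj = np.indices((n, c, ho, wo))
        np.add.at(gxp, (ni, ci, oi * stride + ki, oj * stride + kj), g)
        if padding:
            gxp = gxp[:, :, padding:padding + h, padding:padding + w]
        xt._accum(gxp)

    out = Tensor(out_data)
    out.requires_grad = xt.requires_grad
    if out.requires_grad:
        out._prev = (xt,)
        out._backward = bw
    return out
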