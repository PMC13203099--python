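"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the classification network needs: broadcasted
arithmetic, matmul, reshape/transpose/concat, ReLU/sigmoid/softmax, pooling
and im2col-based 2-D convolution. Gradient correctness is enforced by
finite-difference tests rather than trusted by construction.

Arrays are float32 or float64; python scalars never promote a float32 graph,
so the network can train in single precision while the analysis surface stays
double. The graph is a plain tape: each Tensor records its parents and a
closure that accumulates gradients into them.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- autodiff driver -------------------------------------------------

    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- operator sugar --------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, Tensor):
            return add(self, mul(other, -1.0))
        if isinstance(other, (int, float)):
            return add(self, -float(other))
        return add(self, -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes or None)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---- elementwise ---------------------------------------------------------

def add(a: Tensor, b) -> Tensor:
    """Add a tensor and a tensor/constant; python scalars do not promote
    the dtype (so a float32 graph stays float32)."""
    a = _wrap(a)
    if not isinstance(b, Tensor):
        b_const = float(b) if isinstance(b, (int, float)) else np.asarray(b)
        out_const = a.data + b_const

        def bw_c(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))

        return Tensor(out_const, parents=(a,), backward=bw_c)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a: Tensor, b) -> Tensor:
    a = _wrap(a)
    if not isinstance(b, Tensor):
        b_arr = float(b) if isinstance(b, (int, float)) else np.asarray(b)
        out_data = a.data * b_arr

        def bw_const(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b_arr, a.data.shape))

        return Tensor(out_data, parents=(a,), backward=bw_const)

    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def power(a: Tensor, p: float) -> Tensor:
    a = _wrap(a)
    out_data = a.data ** p

    def bw(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1.0))

    return Tensor(out_data, parents=(a,), backward=bw)


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def exp(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return Tensor(out_data, parents=(a,), backward=bw)


def log(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return Tensor(out_data, parents=(a,), backward=bw)


def relu(a: Tensor) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    return Tensor(out_data, parents=(a,), backward=bw)


def sigmoid(a: Tensor) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bw)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    a = _wrap(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

    return Tensor(out_data, parents=(a,), backward=bw)


# ---- reductions and shape ops -------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=bw)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis, keepdims), 1.0 / count)


def reshape(a: Tensor, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)
    orig = a.data.shape

    def bw(g):
        if a.requires_grad:
            a._accum(g.reshape(orig))

    return Tensor(out_data, parents=(a,), backward=bw)


def transpose(a: Tensor, axes=None) -> Tensor:
    a = _wrap(a)
    out_data = a.data.transpose(axes)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))

    def bw(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return Tensor(out_data, parents=(a,), backward=bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accum(part)

    return Tensor(out_data, parents=tuple(tensors), backward=bw)


def getitem(a: Tensor, idx) -> Tensor:
    a = _wrap(a)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return Tensor(out_data, parents=(a,), backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


# ---- spatial ops ---------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hout = (h + 2 * pad - kh) // stride + 1
    wout = (w + 2 * pad - kw) // stride + 1
    # fill by kh*kw cache-friendly strided copies instead of one big permute
    cols = np.empty((b, c, kh * kw, hout, wout), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = x[:, :, i:i + stride * hout:stride,
                                       j:j + stride * wout:stride]
    return cols.reshape(b, c * kh * kw, hout * wout), hout, wout


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, hout, wout):
    b, c, h, w = xshape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(b, c, kh, kw, hout, wout)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * hout:stride,
                j:j + stride * wout:stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:h + pad, pad:w + pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution; x (B,Cin,H,W), weight (Cout,Cin,kh,kw), bias (Cout,)."""
    x, weight = _wrap(x), _wrap(weight)
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(f"conv2d: input has {x.data.shape[1]} channels, "
                         f"weight expects {cin}")
    cols, hout, wout = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = wmat @ cols  # (b, cout, hout*wout) via broadcasting over batch
    out_data = out.reshape(x.data.shape[0], cout, hout, wout)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gmat = g.reshape(g.shape[0], cout, hout * wout)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 2)))
        if weight.requires_grad:
            dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = wmat.T @ gmat
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad,
                             hout, wout))

    return Tensor(out_data, parents=parents, backward=bw)


def maxpool2d(x: Tensor, k: int) -> Tensor:
    """Max pooling with kernel = stride = k; ties route the gradient to the
    first window position in row-major order."""
    x = _wrap(x)
    b, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial size ({h},{w}) not divisible by {k}")
    offsets = [(i, j) for i in range(k) for j in range(k)]
    out_data = x.data[:, :, ::k, ::k].copy()
    for i, j in offsets[1:]:
        np.maximum(out_data, x.data[:, :, i::k, j::k], out=out_data)

    def bw(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        remaining = np.ones(out_data.shape, dtype=bool)
        for i, j in offsets:
            hit = remaining & (x.data[:, :, i::k, j::k] == out_data)
            dx[:, :, i::k, j::k][hit] = g[hit]
            remaining &= ~hit
        x._accum(dx)

    return Tensor(out_data, parents=(x,), backward=bw)


def avgpool2d(x: Tensor, k: int) -> Tensor:
    """Average pooling with kernel = stride = k."""
    x = _wrap(x)
    b, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avgpool2d: spatial size ({h},{w}) not divisible by {k}")
    ho, wo = h // k, w // k
    out_data = x.data.reshape(b, c, ho, k, wo, k).mean(axis=(3, 5))

    def bw(g):
        if x.requires_grad:
            dx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accum(dx)

    return Tensor(out_data, parents=(x,), backward=bw)
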