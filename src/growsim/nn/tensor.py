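"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small engine sized to the convolutional models in this
package.  Every primitive's vector-Jacobian product is itself expressed in
terms of primitives, so gradients are ordinary graph nodes and
higher-order derivatives (needed for the critic's gradient penalty) come
for free via ``grad(..., create_graph=True)``.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True

#: arrays default to single precision (double precision inputs are
#: preserved, so closed-form checks can run at full precision)
DEFAULT_DTYPE = np.float32


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An n-d array plus optional backward graph bookkeeping."""

    __slots__ = ("data", "requires_grad", "parents", "vjp")

    def __init__(self, data, requires_grad=False, parents=None, vjp=None):
        if isinstance(data, Tensor):
            data = data.data
        if type(data) is float or type(data) is int:
            # exact Python scalars act weakly typed: they adopt the
            # default dtype instead of promoting float32 graphs
            data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.parents = parents if self.requires_grad else None
        self.vjp = vjp if self.requires_grad else None

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, pow_const(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), pow_const(self, -1.0))

    def __pow__(self, p):
        return pow_const(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def transpose(self, axes):
        return transpose(self, axes)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjp):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents), vjp=vjp)


# ---------------------------------------------------------------------
# shape plumbing
# ---------------------------------------------------------------------

def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def broadcast_to(a, shape):
    a = _as_tensor(a)
    shape = tuple(shape)
    data = np.broadcast_to(a.data, shape)

    def vjp(g):
        return (_unbroadcast(g, a.shape),)

    return _make(data, (a,), vjp)


def reshape(a, shape):
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def vjp(g):
        return (reshape(g, a.shape),)

    return _make(data, (a,), vjp)


def transpose(a, axes):
    a = _as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return _make(data, (a,), vjp)


def swap_last(a):
    """Transpose the last two axes (batched matrix transpose)."""
    axes = tuple(range(a.ndim - 2)) + (a.ndim - 1, a.ndim - 2)
    return transpose(a, axes)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        grads = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(getitem(g, tuple(sl)))
        return tuple(grads)

    return _make(data, tensors, vjp)


def getitem(a, idx):
    a = _as_tensor(a)
    data = a.data[idx]

    def vjp(g):
        return (scatter(g, idx, a.shape),)

    return _make(data, (a,), vjp)


def scatter(g, idx, shape):
    """Scatter-add ``g`` into a zero array of ``shape`` at ``idx``."""
    g = _as_tensor(g)
    out = np.zeros(shape, dtype=g.data.dtype)
    np.add.at(out, idx, g.data)

    def vjp(gg):
        return (getitem(gg, idx),)

    return _make(out, (g,), vjp)


# ---------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def vjp(g):
        return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

    return _make(data, (a, b), vjp)


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data - b.data

    def vjp(g):
        return (_unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape))

    return _make(data, (a, b), vjp)


def neg(a):
    a = _as_tensor(a)

    def vjp(g):
        return (neg(g),)

    return _make(-a.data, (a,), vjp)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def vjp(g):
        return (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape))

    return _make(data, (a, b), vjp)


def pow_const(a, p):
    a = _as_tensor(a)
    p = float(p)
    data = a.data ** p

    def vjp(g):
        return (mul(g, mul(Tensor(p), pow_const(a, p - 1.0))),)

    return _make(data, (a,), vjp)


def exp(a):
    a = _as_tensor(a)
    out = _make(np.exp(a.data), (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, out),)
    return out


def log(a):
    a = _as_tensor(a)

    def vjp(g):
        return (mul(g, pow_const(a, -1.0)),)

    return _make(np.log(a.data), (a,), vjp)


def sqrt(a):
    return pow_const(a, 0.5)


def tanh(a):
    a = _as_tensor(a)
    out = _make(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, sub(Tensor(1.0), mul(out, out))),)
    return out


def sigmoid(a):
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(data, (a,), None)
    if out.requires_grad:
        out.vjp = lambda g: (mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def leaky_relu(a, slope=0.2):
    a = _as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return _make(a.data * mask, (a,), vjp)


def relu(a):
    return leaky_relu(a, 0.0)


def silu(a):
    a = _as_tensor(a)
    return mul(a, sigmoid(a))


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.shape

    def vjp(g):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * len(in_shape)), in_shape),)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        axes = tuple(ax % len(in_shape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(in_shape))
            g = reshape(g, kshape)
        return (broadcast_to(g, in_shape),)

    return _make(data, (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires ndim >= 2 operands")
    data = np.matmul(a.data, b.data)

    def vjp(g):
        ga = _unbroadcast(matmul(g, swap_last(b)), a.shape)
        gb = _unbroadcast(matmul(swap_last(a), g), b.shape)
        return (ga, gb)

    return _make(data, (a, b), vjp)


# ---------------------------------------------------------------------
# convolution plumbing (im2col / col2im are mutually adjoint)
# ---------------------------------------------------------------------

def _conv_out_size(h, k, stride, pad):
    return (h + 2 * pad - k) // stride + 1


def im2col(x, k, stride=1, pad=0):
    x = _as_tensor(x)
    n, c, h, w = x.shape
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = _conv_out_size(h, k, stride, pad)
    wo = _conv_out_size(w, k, stride, pad)
    v = sliding_window_view(xd, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, ho * wo
    )

    def vjp(g):
        return (col2im(g, x.shape, k, stride, pad),)

    return _make(cols, (x,), vjp)


def col2im(cols, x_shape, k, stride=1, pad=0):
    cols = _as_tensor(cols)
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = _conv_out_size(h, k, stride, pad)
    wo = _conv_out_size(w, k, stride, pad)
    c6 = cols.data.reshape(n, c, k, k, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.data.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += c6[
                :, :, i, j
            ]
    if pad:
        out = out[:, :, pad : pad + h, pad : pad + w]

    def vjp(g):
        return (im2col(g, k, stride, pad),)

    return _make(np.ascontiguousarray(out), (cols,), vjp)


# ---------------------------------------------------------------------
# backward engine
# ---------------------------------------------------------------------

def _topo(root):
    order, visited, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        if node.parents:
            for p in node.parents:
                if p.requires_grad:
                    stack.append((p, False))
    return order


def grad(output, inputs, grad_output=None, create_graph=False):
    """Gradients of a scalar (or seeded) ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own
    backward graph, enabling differentiation *through* the gradient —
    used by the WGAN gradient penalty.
    """
    if not output.requires_grad:
        raise ValueError("output does not require grad")
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    input_ids = {id(t): i for i, t in enumerate(inputs)}
    gmap = {id(output): grad_output}
    results = [None] * len(inputs)
    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(_topo(output)):
            g = gmap.pop(id(node), None)
            if g is None:
                continue
            if id(node) in input_ids:
                results[input_ids[id(node)]] = g
            if node.parents is None:
                continue
            for p, pg in zip(node.parents, node.vjp(g)):
                if pg is None or not p.requires_grad:
                    continue
                acc = gmap.get(id(p))
                gmap[id(p)] = pg if acc is None else add(acc, pg)
    return results
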