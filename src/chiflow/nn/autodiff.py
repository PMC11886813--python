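"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tensor engine sufficient for the graph-attention denoiser and its
training loop: elementwise arithmetic with broadcasting, matrix products,
reductions, row gather / segment-sum (the message-passing primitives),
layer normalization, and the nonlinearities used by the network.  Gradients
are accumulated by topological-order backpropagation from a scalar loss.

Every primitive's vector-Jacobian product is exercised against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_sum", "layer_norm"]


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # beat ndarray in mixed binary ops

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    def detach(self):
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._node(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._node(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p):
        a = self
        p = float(p)

        def bw(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._node(a.data**p, (a,), bw)

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bw(g):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor._node(a.data @ b.data, (a, b), bw)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        a = self
        return Tensor._node(
            a.data.reshape(*shape), (a,), lambda g: a._accum(g.reshape(a.data.shape))
        )

    # -- elementwise functions ----------------------------------------------

    def sin(self):
        a = self
        return Tensor._node(np.sin(a.data), (a,), lambda g: a._accum(g * np.cos(a.data)))

    def cos(self):
        a = self
        return Tensor._node(np.cos(a.data), (a,), lambda g: a._accum(-g * np.sin(a.data)))

    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._node(out_data, (a,), lambda g: a._accum(g * out_data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._node(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def relu(self):
        a = self
        return Tensor._node(
            np.maximum(a.data, 0.0), (a,), lambda g: a._accum(g * (a.data > 0))
        )

    def gelu(self):
        """tanh-approximation GELU."""
        a = self
        c = np.sqrt(2.0 / np.pi)
        u = c * (a.data + 0.044715 * a.data**3)
        th = np.tanh(u)

        def bw(g):
            du = c * (1.0 + 3 * 0.044715 * a.data**2)
            a._accum(g * (0.5 * (1.0 + th) + 0.5 * a.data * (1.0 - th**2) * du))

        return Tensor._node(0.5 * a.data * (1.0 + th), (a,), bw)

    def softplus(self):
        """log(1 + e^x), numerically stable; used for nonnegative heads."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bw(g):
            a._accum(g / (1.0 + np.exp(-a.data)))

        return Tensor._node(out_data, (a,), bw)


def concat(tensors, axis=-1):
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def gather(x, index):
    """Select rows: ``x[index]`` with scatter-add backward."""
    x = Tensor._lift(x)
    index = np.asarray(index)

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, index, g)
            x._accum(gx)

    return Tensor._node(x.data[index], (x,), bw)


def segment_sum(x, segment_ids, num_segments):
    """Sum rows of ``x`` into ``num_segments`` buckets (scatter-add)."""
    x = Tensor._lift(x)
    segment_ids = np.asarray(segment_ids)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, segment_ids, x.data)

    def bw(g):
        x._accum(g[segment_ids])

    return Tensor._node(out_data, (x,), bw)


def layer_norm(x, weight, bias, eps=1e-5):
    """Normalize the last axis to zero mean / unit variance, then affine."""
    x = Tensor._lift(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    parents = (x, weight, bias)

    def bw(g):
        if weight.requires_grad:
            weight._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if bias.requires_grad:
            bias._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gh = g * weight.data
            n = x.data.shape[-1]
            gx = (
                gh
                - gh.mean(axis=-1, keepdims=True)
                - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x._accum(gx)

    return Tensor._node(xhat * weight.data + bias.data, parents, bw)
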