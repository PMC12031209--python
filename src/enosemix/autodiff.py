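"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a float64
ndarray and records the closure that propagates the adjoint to its inputs.
Only the operations the network needs are implemented (broadcast arithmetic,
matmul, 2-D convolution, reductions, the usual pointwise nonlinearities).
Gradients are checked against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._children: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias a parent's grad buffer or a broadcast view
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def _lift(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0:
            # scalar constants adopt this tensor's dtype (no silent promotion)
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    @staticmethod
    def _node(data, children: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(c.requires_grad for c in children):
            out.requires_grad = True
            out._children = children
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._children:
                if child.requires_grad:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return self._node(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._node(self.data @ other.data, (self, other), backward)

    # -- pointwise nonlinearities ----------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._node(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        return self._node(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        return self._node(e, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions and shape ops ----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(self.data.dtype)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def backward(g):
            if not self.requires_grad:
                return
            gg = g
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis)
            elif not keepdims and axis is None:
                gg = np.broadcast_to(g, out_data.shape)
            self._accumulate(mask * gg)

        data = out_data if keepdims else np.squeeze(out_data, axis=axis) \
            if axis is not None else out_data.reshape(())
        return self._node(data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return self._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int) -> Tensor:
    """2-D cross-correlation with square kernel, stride 1 and zero padding.

    x: (N, C, H, W); w: (O, C, k, k); b: (O,).  Output spatial size is
    H + 2*padding - k + 1 (the network uses k=3, padding=2, which grows each
    side by one pixel per layer).
    """
    n, c, h, wd = x.shape
    o, c2, k, _ = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    p = int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    wmat = w.data.reshape(o, c * k * k)
    out = cols @ wmat.T + b.data  # N, L, O
    out = out.transpose(0, 2, 1).reshape(n, o, ho, wo)

    def backward(g):
        gl = g.reshape(n, o, ho * wo).transpose(0, 2, 1)  # N, L, O
        if b.requires_grad:
            b._accumulate(gl.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("nlo,nlc->oc", gl, cols)
            w._accumulate(gw.reshape(o, c, k, k))
        if x.requires_grad:
            gcols = gl @ wmat  # N, L, C*k*k
            g6 = gcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + ho, j:j + wo] += g6[:, :, :, :, i, j]
            x._accumulate(gxp[:, :, p:p + h, p:p + wd])

    return Tensor._node(out, (x, w, b), backward)
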