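"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the attention-MIL risk network needs:
broadcasting arithmetic, (batched) matrix products, ReLU, exp/log, axis
reductions, softmax, reshape/swapaxes and stacking. Gradients propagate
through a dynamically built tape; see tests for finite-difference checks.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph machinery -----------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order DFS: graphs can be thousands of nodes deep
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        return a._make(a.data + b.data, (a, b), lambda g: (
            _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        return a._make(a.data * b.data, (a, b), lambda g: (
            _unbroadcast(g * b.data, a.data.shape), _unbroadcast(g * a.data, b.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        return a._make(a.data / b.data, (a, b), lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

        return a._make(a.data @ b.data, (a, b), backward)

    # -- nonlinearities and reductions ----------------------------------------
    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)

        return self._make(s, (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def swapaxes(self, a1: int, a2: int):
        return self._make(np.swapaxes(self.data, a1, a2), (self,),
                          lambda g: (np.swapaxes(g, a1, a2),))

    def transpose_last(self):
        return self.swapaxes(-1, -2)


def stack(tensors: list[Tensor]) -> Tensor:
    """Stack scalars/arrays along a new leading axis."""
    datas = np.stack([t.data for t in tensors])
    out = Tensor(datas, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = lambda g: tuple(g[i] for i in range(len(tensors)))
    return out
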