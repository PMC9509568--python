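"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float32 ``numpy.ndarray`` together with an optional
gradient and a backward closure.  Operations defined here and in
:mod:`leafclar.nn.ops` build a computation graph; calling
:meth:`Tensor.backward` on a scalar result propagates gradients to every
reachable tensor with ``requires_grad=True``.

The engine is deliberately small: only the operations the classification
network needs are implemented, each with a hand-written backward pass that is
checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autodiff ----------------------------------------------------------
    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = make_op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return make_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            c = float(other)
            return make_op(self.data * np.float32(c), (self,), lambda g: (g * np.float32(c),))
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        return make_op(
            a.data * b.data,
            (a, b),
            lambda g: (_unbroadcast(g * b.data, a.data.shape), _unbroadcast(g * a.data, b.data.shape)),
        )

    __rmul__ = __mul__

    def sum(self):
        return make_op(
            np.asarray(self.data.sum(), dtype=np.float32),
            (self,),
            lambda g: (np.broadcast_to(g, self.data.shape).astype(np.float32),),
        )

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        return make_op(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))


def make_op(data: np.ndarray, parents: tuple, grad_fn) -> Tensor:
    """Create a graph node.

    ``grad_fn`` maps the output gradient to a tuple of parent gradients
    (``None`` entries are skipped).
    """
    out = Tensor.__new__(Tensor)
    out.data = np.asarray(data, dtype=np.float32)
    out.grad = None
    out._backward = None
    out._parents = ()
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out.requires_grad = req
    if req:
        out._parents = tuple(parents)

        def _bw(g, parents=parents, grad_fn=grad_fn):
            grads = grad_fn(g)
            for p, pg in zip(parents, grads):
                if pg is not None and p.requires_grad:
                    p.accumulate(pg)

        out._backward = _bw
    return out
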