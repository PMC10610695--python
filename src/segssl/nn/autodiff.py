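"""Tape-based reverse-mode autodiff on numpy arrays.

Only the primitives the package needs are implemented: arithmetic with
broadcasting, matmul, exp/log/sqrt/relu, reductions (sum/mean/max), shape ops
(reshape/transpose/slice/fancy index/concatenate). Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "grad_check"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    @property
    def ndim(self) -> int:
        return self.value.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.value)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # own a copy: g may be a view shared with a sibling's gradient
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        if grad is None:
            grad = np.ones_like(self.value)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.value + other.value, _parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.value, _parents=(self,))

        def backward(g: np.ndarray) -> None:
            self._accumulate(-g)

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.value * other.value, _parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self**-1.0

    def __pow__(self, p: float) -> "Tensor":
        p = float(p)
        out = Tensor(self.value**p, _parents=(self,))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * p * self.value ** (p - 1.0))

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.value @ other.value, _parents=(self, other))

        def backward(g: np.ndarray) -> None:
            a, b = self.value, other.value
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(g, b)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g if a.ndim > 1 else np.outer(a, g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    # -------------------------------------------------------------- pointwise

    def exp(self) -> "Tensor":
        val = np.exp(self.value)
        out = Tensor(val, _parents=(self,))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * val)

        out._backward = backward if out.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.value), _parents=(self,))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.value)

        out._backward = backward if out.requires_grad else None
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def relu(self) -> "Tensor":
        mask = self.value > 0
        out = Tensor(self.value * mask, _parents=(self,))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * mask)

        out._backward = backward if out.requires_grad else None
        return out

    # -------------------------------------------------------------- reductions

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.value.size if axis is None else np.prod(
            [self.shape[a] for a in (np.atleast_1d(axis) % self.ndim)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the (first) argmax."""
        val = self.value.max(axis=axis, keepdims=keepdims)
        # route gradient to a single winner per slice (first argmax on ties)
        winner = np.expand_dims(self.value.argmax(axis=axis), axis)
        hot = np.zeros(self.shape, dtype=bool)
        np.put_along_axis(hot, winner, True, axis=axis)
        out = Tensor(val, _parents=(self,))

        def backward(g: np.ndarray) -> None:
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(hot * g)

        out._backward = backward if out.requires_grad else None
        return out

    def logsumexp(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Numerically stable log(sum(exp(x))) built from primitives."""
        m = Tensor(self.value.max(axis=axis, keepdims=True))  # constant shift
        shifted = (self - m).exp().sum(axis=axis, keepdims=True).log() + m
        if keepdims:
            return shifted
        return shifted.reshape(np.delete(np.array(shifted.shape), axis))

    # --------------------------------------------------------------- shape ops

    def reshape(self, shape) -> "Tensor":
        shape = tuple(int(s) for s in np.atleast_1d(shape))
        out = Tensor(self.value.reshape(shape), _parents=(self,))

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(self.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def transpose(self, axes=None) -> "Tensor":
        out = Tensor(self.value.transpose(axes), _parents=(self,))
        inv = None if axes is None else np.argsort(axes)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.transpose(inv))

        out._backward = backward if out.requires_grad else None
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.value[idx], _parents=(self,))

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = backward if out.requires_grad else None
        return out

    def take_rows(self, rows: np.ndarray, cols: np.ndarray) -> "Tensor":
        """Gather ``self[rows[i], cols[i]]`` (paired fancy index)."""
        return self[(np.asarray(rows), np.asarray(cols))]

    def normalize(self, axis: int = -1, eps: float = 1e-12) -> "Tensor":
        """L2-normalize along ``axis``."""
        norm = ((self * self).sum(axis=axis, keepdims=True) + eps).sqrt()
        return self / norm


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        _parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward if out.requires_grad else None
    return out


def grad_check(
    fn: Callable[..., Tensor],
    params: Sequence[Tensor],
    eps: float = 1e-6,
) -> float:
    """Max |analytic − central-difference| gradient error over ``params``.

    ``fn`` must return a scalar Tensor computed from ``params``.
    """
    for p in params:
        p.zero_grad()
    out = fn()
    out.backward()
    worst = 0.0
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.value)
        flat = p.value.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn().item()
            flat[i] = orig - eps
            lo = fn().item()
            flat[i] = orig
            num = (hi - lo) / (2 * eps)
            worst = max(worst, abs(num - analytic.ravel()[i]))
    return worst
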