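"""Compact reverse-mode automatic differentiation on numpy arrays.

The denoising network in this package is small (a few dozen dense maps), so a
full deep-learning framework is unnecessary: this module provides a ``Tensor``
wrapper around ``numpy.ndarray`` that records a computation tape and plays it
backwards, plus an Adam optimizer.  Only the operations the network actually
uses are implemented (broadcast-aware arithmetic, matmul, reductions, ReLU,
sigmoid, exp/log, slicing).  All arrays are float64.

Gradient conventions
--------------------
* Broadcasting in binary ops is undone in the backward pass by summing the
  upstream gradient over broadcast axes (``_unbroadcast``).
* ``clip_min`` uses the subgradient that is zero on the clipped region; it is
  only used as a numerical guard inside logs and divisions.
* Graphs are built eagerly; ``backward()`` topologically sorts the tape once.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, List, Optional, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, "Tensor"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference-time memory)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the closure needed to backpropagate into parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd machinery --------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- binary ops ----------------------------------------------------------
    @staticmethod
    def _lift(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other: ArrayLike, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(fwd(self.data, other.data))
        needs = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        if needs:
            out.requires_grad = True
            out._parents = (self, other)

            def _bw(g: np.ndarray, a=self, b=other) -> None:
                if a.requires_grad:
                    a._accumulate(_unbroadcast(bwd_self(g, a.data, b.data), a.shape))
                if b.requires_grad:
                    b._accumulate(_unbroadcast(bwd_other(g, a.data, b.data), b.shape))

            out._backward = _bw
        return out

    def __add__(self, other: ArrayLike) -> "Tensor":
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other: ArrayLike) -> "Tensor":
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p)
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _bw(g: np.ndarray, a=self) -> None:
                a._accumulate(g * p * a.data ** (p - 1))

            out._backward = _bw
        return out

    def matmul(self, other: ArrayLike) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data))
        if _GRAD_ENABLED and (self.requires_grad or other.requires_grad):
            out.requires_grad = True
            out._parents = (self, other)

            def _bw(g: np.ndarray, a=self, b=other) -> None:
                if a.requires_grad:
                    if b.data.ndim == 1:
                        ga = g[..., None] * b.data
                    else:
                        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                    a._accumulate(_unbroadcast(ga, a.shape))
                if b.requires_grad:
                    if a.data.ndim == 1:
                        gb = np.outer(a.data, g) if g.ndim == 1 else a.data[:, None] * g
                    else:
                        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                    b._accumulate(_unbroadcast(gb, b.shape))

            out._backward = _bw
        return out

    __matmul__ = matmul

    # -- unary ops -----------------------------------------------------------
    def _unary(self, fwd, bwd) -> "Tensor":
        out = Tensor(fwd(self.data))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _bw(g: np.ndarray, a=self, o=out) -> None:
                a._accumulate(bwd(g, a.data, o.data))

            out._backward = _bw
        return out

    def relu(self) -> "Tensor":
        return self._unary(lambda a: np.maximum(a, 0.0),
                           lambda g, a, o: g * (a > 0))

    def sigmoid(self) -> "Tensor":
        def _fwd(a):
            with np.errstate(over="ignore"):  # saturates cleanly to 0/1
                return 1.0 / (1.0 + np.exp(-a))
        return self._unary(_fwd, lambda g, a, o: g * o * (1.0 - o))

    def exp(self) -> "Tensor":
        return self._unary(np.exp, lambda g, a, o: g * o)

    def log(self) -> "Tensor":
        return self._unary(np.log, lambda g, a, o: g / a)

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def clip_min(self, lo: float) -> "Tensor":
        return self._unary(lambda a: np.maximum(a, lo),
                           lambda g, a, o: g * (a > lo))

    # -- reshaping & indexing ------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _bw(g: np.ndarray, a=self) -> None:
                a._accumulate(g.reshape(orig))

            out._backward = _bw
        return out

    def swapaxes(self, a1: int, a2: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a1, a2))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _bw(g: np.ndarray, a=self) -> None:
                a._accumulate(np.swapaxes(g, a1, a2))

            out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx])
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)

            def _bw(g: np.ndarray, a=self) -> None:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

            out._backward = _bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if _GRAD_ENABLED and self.requires_grad:
            out.requires_grad = True
            out._parents = (self,)
            shape = self.data.shape

            def _bw(g: np.ndarray, a=self) -> None:
                if axis is None:
                    a._accumulate(np.broadcast_to(g, shape).astype(np.float64))
                    return
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, tuple(ax % len(shape) for ax in axes))
                a._accumulate(np.broadcast_to(g, shape).astype(np.float64))

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def parameter(data: np.ndarray) -> Tensor:
    """A leaf tensor that accumulates gradients."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None


class Adam:
    """Adam optimizer over a name->Tensor parameter mapping."""

    def __init__(self, params: Dict[str, Tensor], lr: float = 2e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self, only: Optional[Iterable[str]] = None) -> None:
        """Apply one update; `only` restricts the update to the named blocks."""
        self.t += 1
        names = set(only) if only is not None else None
        for k, p in self.params.items():
            if p.grad is None:
                continue
            if names is not None and k not in names:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        zero_grads(self.params.values())
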