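"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine implements exactly the primitives the network needs: broadcasted
arithmetic, (batched) matmul, elementwise nonlinearities, axis reductions,
shape manipulation, concatenation and slicing.  Convolution, pooling and the
normalisation layers register their own backward rules in
:mod:`segresdeit.nn` through :func:`make_node`.

All data is float64.  Gradients accumulate into ``Tensor.grad`` so several
``backward()`` calls between ``zero_grad`` implement gradient accumulation.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import special as _sp_special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- basic protocol ----------------------------------------------------

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

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ----------------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Reverse-mode sweep from this tensor.

        `grad` defaults to ones (so scalar losses need no argument).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node._accumulate(g)
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = np.asarray(pg, dtype=np.float64)
        # leaves visited through `grads` dict above only if backward present;
        # flush any remaining leaf grads
        for node in topo:
            g = grads.pop(id(node), None)
            if g is not None and node.requires_grad and node._backward is None:
                node._accumulate(g)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return make_node(
            out_data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return make_node(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        return make_node(
            out_data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data
        return make_node(
            out_data,
            (self, other),
            lambda g: [
                (self, _unbroadcast(g / other.data, self.shape)),
                (other, _unbroadcast(-g * self.data / other.data**2, other.shape)),
            ],
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)
        out_data = self.data**exponent
        return make_node(
            out_data,
            (self,),
            lambda g: [(self, g * exponent * self.data ** (exponent - 1))],
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        if self.ndim < 2 or other.ndim < 2:
            raise ValueError("matmul requires operands of rank >= 2")
        out_data = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return [
                (self, _unbroadcast(ga, self.shape)),
                (other, _unbroadcast(gb, other.shape)),
            ]

        return make_node(out_data, (self, other), backward)

    # -- elementwise -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return make_node(out_data, (self,), lambda g: [(self, g * out_data)])

    def log(self):
        return make_node(np.log(self.data), (self,), lambda g: [(self, g / self.data)])

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return make_node(out_data, (self,), lambda g: [(self, g * 0.5 / out_data)])

    def relu(self):
        mask = self.data > 0
        return make_node(self.data * mask, (self,), lambda g: [(self, g * mask)])

    def sigmoid(self):
        out_data = _sp_special.expit(self.data)
        return make_node(
            out_data, (self,), lambda g: [(self, g * out_data * (1.0 - out_data))]
        )

    def tanh(self):
        out_data = np.tanh(self.data)
        return make_node(
            out_data, (self,), lambda g: [(self, g * (1.0 - out_data**2))]
        )

    def gelu(self):
        """Exact (erf) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _sp_special.erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2.0 * np.pi)
        return make_node(x * cdf, (self,), lambda g: [(self, g * (cdf + x * pdf))])

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        return make_node(
            np.clip(self.data, lo, hi), (self,), lambda g: [(self, g * mask)]
        )

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return [(self, np.broadcast_to(g, self.shape).copy())]
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % self.ndim for a in ax))
            return [(self, np.broadcast_to(g, self.shape).copy())]

        return make_node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return make_node(
            self.data.reshape(shape), (self,), lambda g: [(self, g.reshape(old))]
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return make_node(
            self.data.transpose(axes),
            (self,),
            lambda g: [(self, g.transpose(inv))],
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return [(self, full)]

        return make_node(out_data, (self,), backward)

    # numpy-style helpers used by layers
    def flatten_from(self, start: int):
        return self.reshape(self.shape[:start] + (-1,))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_node(
    data: np.ndarray,
    parents: Sequence[Tensor],
    backward: Callable[[np.ndarray], list],
) -> Tensor:
    """Create an op-output tensor; backward maps output-grad -> [(parent, grad)]."""
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        return list(zip(tensors, pieces))

    return make_node(out_data, tensors, backward)


def stack_detached_max(x: Tensor, axis: int) -> np.ndarray:
    """Detached per-axis max, for numerically stable softmax."""
    return x.data.max(axis=axis, keepdims=True)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(stack_detached_max(x, axis))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
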