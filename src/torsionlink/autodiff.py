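"""Small reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the message-passing encoders and the pair
decoder need: broadcasting arithmetic, matmul, row gather, concatenation,
reductions, sigmoid / ReLU / leaky-ReLU, exp and log.  Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the dimensions that numpy broadcasting expanded."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_fns: tuple = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _result(data, parents_and_fns) -> "Tensor":
        parents = tuple(p for p, _ in parents_and_fns)
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._grad_fns = tuple(fn for _, fn in parents_and_fns)
        return out

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self) -> "Tensor":
        return Tensor._result(self.data.T, [(self, lambda g: g.T)])

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        return Tensor._result(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        return Tensor._result(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor._result(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return Tensor._result(
            self.data / other.data,
            [
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(-g * self.data / other.data**2, other.data.shape),
                ),
            ],
        )

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        return Tensor._result(
            self.data**exponent,
            [(self, lambda g: g * exponent * self.data ** (exponent - 1))],
        )

    def __matmul__(self, other):
        other = Tensor._lift(other)
        return Tensor._result(
            self.data @ other.data,
            [
                (self, lambda g: g @ other.data.T),
                (other, lambda g: self.data.T @ g),
            ],
        )

    # -- nonlinearities -----------------------------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._result(s, [(self, lambda g: g * s * (1.0 - s))])

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._result(self.data * mask, [(self, lambda g: g * mask)])

    def leaky_relu(self, alpha: float = 0.2) -> "Tensor":
        slope = np.where(self.data > 0, 1.0, alpha)
        return Tensor._result(self.data * slope, [(self, lambda g: g * slope)])

    def exp(self) -> "Tensor":
        e = np.exp(np.clip(self.data, -700, 700))
        return Tensor._result(e, [(self, lambda g: g * e)])

    def log(self) -> "Tensor":
        return Tensor._result(np.log(self.data), [(self, lambda g: g / self.data)])

    # -- reductions & reshaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor._result(out_data, [(self, bwd)])

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        return Tensor._result(
            self.data.reshape(*shape), [(self, lambda g: g.reshape(self.data.shape))]
        )

    def gather(self, idx) -> "Tensor":
        """Select rows by integer index; gradients scatter-add back."""
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            return acc

        return Tensor._result(self.data[idx], [(self, bwd)])

    # -- backward pass ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, iter(node._parents))]
            if id(node) in visited:
                return
            visited.add(id(node))
            while stack:
                current, parents = stack[-1]
                advanced = False
                for p in parents:
                    if id(p) not in visited:
                        visited.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(current)
                    stack.pop()

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in zip(node._parents, node._grad_fns):
                if not parent.requires_grad:
                    continue
                pg = fn(g)
                key = id(parent)
                if parent._parents:
                    grads[key] = pg if key not in grads else grads[key] + pg
                else:
                    parent.grad = pg if parent.grad is None else parent.grad + pg

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis; gradients split back."""
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_bwd(i):
        sl = [slice(None)] * datas[i].ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        return lambda g: g[tuple(sl)]

    return Tensor._result(
        np.concatenate(datas, axis=axis),
        [(t, make_bwd(i)) for i, t in enumerate(tensors)],
    )
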