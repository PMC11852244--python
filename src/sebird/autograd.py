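"""A small reverse-mode automatic-differentiation engine over numpy.

Just enough operator coverage for a transformer encoder: broadcasting
arithmetic, batched matmul, reshape/transpose, gather (embedding
lookup), exp/log/tanh/sqrt, reductions, and a numerically stable
softmax/log-softmax. Gradients are accumulated by reverse topological
sweep from a scalar loss. Verified against central finite differences
in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: Array) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=backward)

    def __pow__(self, exponent: float) -> "Tensor":
        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=backward)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)

        def backward(g: Array) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=backward)

    # ---- elementwise functions ------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self) -> "Tensor":
        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        old = self.data.shape

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def transpose(self, *axes: int) -> "Tensor":
        inverse = np.argsort(axes)

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(np.transpose(g, inverse))

        return Tensor(np.transpose(self.data, axes), parents=(self,), backward=backward)

    def __getitem__(self, key) -> "Tensor":
        def backward(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        return Tensor(self.data[key], parents=(self,), backward=backward)

    def take_rows(self, indices: Array) -> "Tensor":
        """Embedding lookup: rows of a 2-D table by an integer index array."""
        indices = np.asarray(indices)

        def backward(g: Array) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, indices.reshape(-1), g.reshape(-1, self.data.shape[-1]))
                self._accum(full)

        return Tensor(self.data[indices], parents=(self,), backward=backward)

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            parents=(self,),
            backward=backward,
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ---- composites ------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self + Tensor(-self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self + Tensor(-self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # ---- backward sweep --------------------------------------------------

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node._parents:  # free intermediate grads eagerly
                    node.grad = None


def gelu(x: Tensor) -> Tensor:
    """GELU with the tanh approximation (NewGELU)."""
    c = np.sqrt(2.0 / np.pi)
    inner = (x + x * x * x * 0.044715) * c
    return x * 0.5 * (inner.tanh() + 1.0)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-12) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gamma + beta


def parameters_zero_grad(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None
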