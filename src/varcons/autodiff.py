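"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery to express and train the recurrent pathogenicity
network: 2-D matrix multiplication, broadcast addition, elementwise
multiplication, tanh/sigmoid/ReLU, column slicing and concatenation,
inverted dropout and a fused softmax cross-entropy loss. Gradients are
accumulated by walking the tape in reverse topological order; correctness
is checked against finite differences in the test suite.

Everything is float32 and eager; there is no broadcasting beyond what the
network needs (bias rows against batches).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "matmul", "concat", "sigmoid", "tanh", "relu",
           "dropout", "softmax_cross_entropy", "softmax"]


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- graph traversal ---------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of a scalar loss into every parameter."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for p in node.parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- ops ---------------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def __mul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=backward)

    def cols(self, a: int, b: int) -> "Tensor":
        """Column slice [:, a:b]."""
        out_data = self.data[:, a:b]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, a:b] = g
                self._accum(full)

        return Tensor(out_data, parents=(self,), backward=backward)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape it was broadcast from."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the last (feature) axis."""
    out_data = np.concatenate([t.data for t in tensors], axis=-1)
    widths = [t.data.shape[-1] for t in tensors]

    def backward(g):
        offset = 0
        for t, w in zip(tensors, widths):
            if t.requires_grad:
                t._accum(g[..., offset:offset + w])
            offset += w

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    return Tensor(t, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or rate is 0."""
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain array (inference path)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    eps = np.float32(1e-12)
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accum(g * grad / np.float32(n))

    return Tensor(np.float32(loss), parents=(logits,), backward=backward)
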