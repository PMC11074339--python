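"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the recurrent VAE needs: affine maps,
elementwise sigmoid/tanh/exp, broadcasting adds, concatenation, masked
blending, embedding lookup, and a fused softmax cross-entropy. Gradients
are accumulated by topological backward traversal, as in any tape-based
framework, with explicit un-broadcasting for bias terms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "cross_entropy", "embedding_lookup"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._backward = None
        self._parents = parents
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- arithmetic -------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * Tensor(-1.0))

    def __rmul__(self, other):
        return self * other

    def __radd__(self, other):
        return self + other

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    # ---- elementwise nonlinearities ---------------------------------
    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = backward
        return out

    def square(self) -> "Tensor":
        out = Tensor(self.data**2, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * 2.0 * self.data)

        out._backward = backward
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g)))

        out._backward = backward
        return out

    # ---- backprop ---------------------------------------------------
    def backward(self):
        """Reverse-traverse the graph from this (scalar) node."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for long sequences
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = backward
    return out


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather: (V, E) table indexed by integer ids of any shape."""
    out = Tensor(table.data[ids], parents=(table,))

    def backward(g):
        if table.requires_grad:
            acc = np.zeros_like(table.data)
            np.add.at(acc, ids, g)
            table._accum(acc)

    out._backward = backward
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Weighted token-level cross-entropy, summed (not averaged).

    logits: (B, V); targets: (B,) int; weights: (B,) float mask.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    nll = -np.log(probs[np.arange(len(targets)), targets] + 1e-300)
    out = Tensor((nll * weights).sum(), parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(len(targets)), targets] -= 1.0
            logits._accum(float(g) * grad * weights[:, None])

    out._backward = backward
    return out


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 3e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, grad_clip: float = 50.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in self.params.items()}
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, self.grad_clip / (norm + 1e-12))
        for k, p in self.params.items():
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
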