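"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine: just enough operations to express the
contextual encoder, the convolutional mention encoder and the task heads used
elsewhere in the package, while exposing gradients with respect to *inputs*
(needed for adversarial perturbation of token embeddings) as well as weights.

Every op builds a node in a dynamic graph; :meth:`Tensor.backward` runs a
topological sweep accumulating ``grad`` on every node reached, so intermediate
nodes (e.g. an embedding lookup) can be inspected for their gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "softmax", "logsumexp", "cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _ensure_grad(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        return self.grad

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            self._ensure_grad()
            other._ensure_grad()
            self.grad += _unbroadcast(g, self.data.shape)
            other.grad += _unbroadcast(g, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += -g

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            self._ensure_grad()
            other._ensure_grad()
            self.grad += _unbroadcast(g * other.data, self.data.shape)
            other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += g * exponent * self.data ** (exponent - 1.0)

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            self._ensure_grad()
            other._ensure_grad()
            self.grad += g @ other.data.T
            other.grad += self.data.T @ g

        out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += g * out.data

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += g / self.data

        out._backward = backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += g * (1.0 - out.data ** 2)

        out._backward = backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += g * (self.data > 0.0)

        out._backward = backward
        return out

    # -- reductions & shaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            self._ensure_grad()
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += g.reshape(self.data.shape)

        out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, (self,))

        def backward(g):
            self._ensure_grad()
            self.grad += g.T

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def backward(g):
            self._ensure_grad()
            np.add.at(self.grad, idx, g)

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._ensure_grad()
        self.grad += np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


# ----------------------------------------------------------------------
# free functions
# ----------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t._ensure_grad()
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.grad += g[tuple(sl)]

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    return x.relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant: no gradient needed
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilised log-sum-exp along ``axis`` (keepdims=False)."""
    shift_data = x.data.max(axis=axis, keepdims=True)
    shift = Tensor(shift_data)
    s = (x - shift).exp().sum(axis=axis, keepdims=True).log() + shift
    # drop the reduced axis
    squeezed = s.reshape(*np.squeeze(s.data, axis=axis).shape)
    return squeezed


def cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean token-level cross entropy.

    ``logits``: (T, C); ``targets``: (T,) int class ids; ``mask``: optional
    boolean (T,) — positions with ``False`` are excluded from the loss.
    """
    targets = np.asarray(targets, dtype=np.intp)
    T = logits.data.shape[0]
    lse = logsumexp(logits, axis=1)
    gold = logits[(np.arange(T), targets)]
    losses = lse - gold
    if mask is not None:
        w = np.asarray(mask, dtype=np.float64)
        if w.sum() == 0:
            return Tensor(0.0)
        return (losses * Tensor(w)).sum() * (1.0 / w.sum())
    return losses.mean()


class Adam:
    """Adam optimiser over a list of leaf parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
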