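"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the classification heads (dense softmax,
bidirectional LSTM, fully connected layers with dropout and L2): tensors
wrap numpy arrays, record the operations that produced them, and
``backward`` runs the chain rule over the topologically sorted graph.
Broadcasting in ``+``/``*`` is handled by summing gradients over broadcast
axes. Deliberately small — not a general-purpose framework.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # ---- ops -------------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - y**2))

        return self._make(y, (self,), backward)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accum(g * y * (1.0 - y))

        return self._make(y, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)

    def concat(self, other: "Tensor", axis: int = -1) -> "Tensor":
        other = self._lift(other)
        n = self.data.shape[axis]

        def backward(g):
            ga, gb = np.split(g, [n], axis=axis)
            self._accum(ga)
            other._accum(gb)

        return self._make(np.concatenate([self.data, other.data], axis=axis), (self, other), backward)

    def sum(self) -> "Tensor":
        def backward(g):
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(), (self,), backward)

    def mean_axis(self, axis: int) -> "Tensor":
        n = self.data.shape[axis]

        def backward(g):
            self._accum(np.repeat(np.expand_dims(g / n, axis), n, axis=axis))

        return self._make(self.data.mean(axis=axis), (self,), backward)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout (training-time only)."""
        if p <= 0.0:
            return self
        mask = (rng.random(self.shape) >= p) / (1.0 - p)

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # ---- backprop --------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns (scalar loss tensor, probability matrix). Gradient is the fused
    stable form ``(softmax - onehot) / batch``.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    nll = -np.log(probs[np.arange(n), labels] + 1e-300).mean()

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(g * grad / n)

    out = Tensor(nll, requires_grad=logits.requires_grad)
    if out.requires_grad:
        out._parents = (logits,)
        out._backward = backward
    return out, probs


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
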