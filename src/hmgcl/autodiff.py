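"""Minimal tape-based reverse-mode automatic differentiation over NumPy.

Supports exactly the operations the encoder, projector, losses and
predictor heads need: broadcasting arithmetic, matmul, row gather,
concatenation, reductions, and the elementwise nonlinearities.  Gradients
are accumulated by a topological backward sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` back down to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = tuple(prev)

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, prev=prev if req else ())
        if req:
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))
        return self._make(self.data ** p, (self,), backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.T)
        return self._make(self.data.T, (self,), backward)

    def gather_rows(self, idx) -> "Tensor":
        idx = np.asarray(idx, dtype=int)
        def backward(g, a=self, i=idx):
            if a.requires_grad:
                grad = np.zeros_like(a.data)
                np.add.at(grad, i, g)
                a._accum(grad)
        return self._make(self.data[idx], (self,), backward)

    # -- reductions & nonlinearities ---------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - o**2))
        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data >= 0, 1.0, slope)
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)
        return self._make(self.data * mask, (self,), backward)

    def relu(self):
        return self.leaky_relu(slope=0.0)

    # -- autodiff driver ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req, prev=tuple(tensors) if req else ())
    if req:
        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = backward
    return out


def stack_rows(rows: list[Tensor]) -> Tensor:
    """Stack 1-D tensors (or 1×d tensors) into a matrix."""
    return concat([r.reshape(1, -1) for r in rows], axis=0)


def parameter(rng: np.random.Generator, shape: tuple[int, ...],
              fan_in: int | None = None) -> Tensor:
    """Seeded uniform init scaled by fan-in."""
    fan = fan_in if fan_in is not None else shape[0]
    bound = 1.0 / np.sqrt(max(fan, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Adam:
    """Adaptive-moment optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * p.grad**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
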