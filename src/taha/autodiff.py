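"""Minimal reverse-mode automatic differentiation over numpy arrays.

The models trained in this package are small Vision Transformers (a few
thousand to a few hundred thousand parameters), so a compact tape-based
engine over dense ``numpy`` arrays is sufficient and keeps the whole
training stack dependency-light and bitwise reproducible.

Only the operations the transformer forward pass needs are implemented:
broadcast arithmetic, (batched) matmul, exp/log/tanh/erf, reductions,
reshape/transpose/slicing/concat, plus composed ``softmax``,
``log_softmax`` and ``layer_norm`` helpers.  Gradients are accumulated in
float64 throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concat", "softmax", "log_softmax", "gelu", "layer_norm", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from long training loops can be deep
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data), self._needs(other), (self, other))

        def _bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = _bw
        return out

    # -- elementwise transcendentals --------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * (1.0 - out.data**2)
        )
        return out

    def erf(self):
        out = Tensor(_sp.erf(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g * 2.0 / np.sqrt(np.pi) * np.exp(-self.data**2)
        )
        return out

    # -- reductions and shape ops ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def transpose(self, *axes):
        ax = axes if axes else None
        out = Tensor(self.data.transpose(ax), self.requires_grad, (self,))
        inv = np.argsort(ax) if ax else None
        out._backward = lambda g: self.requires_grad and self._accum(
            g.transpose(inv) if inv is not None else g.transpose()
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-subtraction for numerical stability; the shift is a constant w.r.t. grad
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-function GELU."""
    return x * 0.5 * ((x / np.sqrt(2.0)).erf() + 1.0)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * gamma + beta


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 3e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
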