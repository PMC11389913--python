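"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the forecasting models need: broadcasting
arithmetic, matmul (with stacked batch dimensions), the sigmoid/tanh/relu
nonlinearities, reductions, reshapes, concatenation and indexing.  Gradients
are accumulated by a topological-order sweep from the output node.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "sigmoid", "tanh", "relu", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that built it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        # no in-place update: incoming grads may alias other nodes' buffers
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- graph construction helper -------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward(out)
        return out

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(out):
            def run():
                self._accumulate(_unbroadcast(out.grad, self.shape))
                other._accumulate(_unbroadcast(out.grad, other.shape))
            return run

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(out):
            def run():
                self._accumulate(-out.grad)
            return run

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(out):
            def run():
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))
            return run

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(out):
            def run():
                self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
                other._accumulate(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )
            return run

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")

        def bw(out):
            def run():
                self._accumulate(out.grad * p * self.data ** (p - 1))
            return run

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(out):
            def run():
                ga = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                gb = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                self._accumulate(_unbroadcast(ga, self.shape))
                other._accumulate(_unbroadcast(gb, other.shape))
            return run

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(out):
            def run():
                self._accumulate(out.grad.reshape(self.shape))
            return run

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bw(out):
            def run():
                self._accumulate(np.swapaxes(out.grad, a, b))
            return run

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(out):
            def run():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)
            return run

        return Tensor._make(self.data[idx], (self,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(out):
            def run():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            return run

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -----------------------------------------
    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def bw(out):
            def run():
                self._accumulate(out.grad * (1.0 - t * t))
            return run

        return Tensor._make(t, (self,), bw)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(out):
            def run():
                self._accumulate(out.grad * s * (1.0 - s))
            return run

        return Tensor._make(s, (self,), bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(out):
            def run():
                self._accumulate(out.grad * mask)
            return run

        return Tensor._make(self.data * mask, (self,), bw)

    def exp(self) -> "Tensor":
        e = np.exp(self.data)

        def bw(out):
            def run():
                self._accumulate(out.grad * e)
            return run

        return Tensor._make(e, (self,), bw)

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)

        def bw(out):
            def run():
                self._accumulate(out.grad * 0.5 / r)
            return run

        return Tensor._make(r, (self,), bw)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(out):
        def run():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(idx)])
        return run

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(out):
        def run():
            for k, t in enumerate(tensors):
                t._accumulate(np.take(out.grad, k, axis=axis))
        return run

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def sigmoid(x: Tensor) -> Tensor:
    return as_tensor(x).sigmoid()


def tanh(x: Tensor) -> Tensor:
    return as_tensor(x).tanh()


def relu(x: Tensor) -> Tensor:
    return as_tensor(x).relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift for numerical stability; the shift is a constant w.r.t. grads
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ----------------------------------------------------------------------
# Module / parameter plumbing
# ----------------------------------------------------------------------


class Module:
    """Parameter container with recursive traversal and a train/eval flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()
        self._collect(self, out, seen)
        return out

    @staticmethod
    def _collect(obj, out: list[Tensor], seen: set[int]) -> None:
        if id(obj) in seen:
            return
        seen.add(id(obj))
        if isinstance(obj, Tensor):
            if obj.requires_grad:
                out.append(obj)
            return
        if isinstance(obj, Module):
            for v in vars(obj).values():
                Module._collect(v, out, seen)
            return
        if isinstance(obj, (list, tuple)):
            for v in obj:
                Module._collect(v, out, seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> None:
        self._set_mode(True)

    def eval(self) -> None:
        self._set_mode(False)

    def _set_mode(self, flag: bool) -> None:
        self.training = flag
        for v in vars(self).values():
            for m in _iter_modules(v):
                m._set_mode(flag)

    # parameter state as flat numpy copies (for checkpoint/restore)
    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Iterable[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


def _iter_modules(obj):
    if isinstance(obj, Module):
        yield obj
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _iter_modules(v)


class Linear(Module):
    """Affine map with uniform(-1/sqrt(fan_in), +) initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, size=(n_out,)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask rng is injected per call
    via the module's `rng` attribute so training runs stay reproducible."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0 or self.rng is None:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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


class SGD:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
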