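"""A compact reverse-mode automatic differentiation engine on numpy.

Covers exactly the operations the graph networks need: broadcasted
arithmetic, (batched) matrix products, reductions, elementwise
nonlinearities, masked softmax and log-softmax, transpose/reshape/concat.
Gradients are validated against central finite differences in the test
suite. Not a general deep-learning framework — a deliberately small tape.
"""

from __future__ import annotations

import numpy as np

#: Working precision for all tensors. float32 keeps the dense batched
#: graph operations cheap; switch to float64 (``set_dtype``) when checking
#: gradients against finite differences.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = dtype


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
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
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ---------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, e):
        return power(self, e)


def ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    if any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b) -> Tensor:
    a, b = ensure(a), ensure(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = ensure(a), ensure(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def power(a, e: float) -> Tensor:
    a = ensure(a)
    out_data = a.data**e

    def backward(g):
        a._accumulate(g * e * a.data ** (e - 1))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = ensure(a), ensure(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# reductions & shape


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = ensure(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = ensure(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def transpose(a, axes) -> Tensor:
    a = ensure(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _make(np.transpose(a.data, axes), (a,), backward)


def reshape(a, shape) -> Tensor:
    a = ensure(a)
    orig = a.shape

    def backward(g):
        a._accumulate(g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [ensure(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# nonlinearities


def relu(a) -> Tensor:
    a = ensure(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def leaky_relu(a, alpha: float = 0.2) -> Tensor:
    a = ensure(a)
    out_data = np.where(a.data > 0, a.data, alpha * a.data)

    def backward(g):
        a._accumulate(g * np.where(a.data > 0, 1.0, alpha))

    return _make(out_data, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = ensure(a)
    # exp only on the negative branch to avoid float32 overflow
    out_data = np.where(a.data > 0, a.data, alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0))

    def backward(g):
        a._accumulate(g * np.where(a.data > 0, 1.0, out_data + alpha))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = ensure(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a) -> Tensor:
    a = ensure(a)
    t = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), backward)


def log(a) -> Tensor:
    a = ensure(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


# ---------------------------------------------------------------------------
# softmax family


def masked_softmax(logits, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over entries where ``mask`` is True; zero elsewhere.

    Rows with no valid entry yield all-zero output (and zero gradient).
    """
    a = ensure(logits)
    mask = np.broadcast_to(np.asarray(mask, bool), a.shape)
    neg = np.where(mask, a.data, -np.inf)
    mx = np.max(neg, axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    ex = np.where(mask, np.exp(neg - mx), 0.0)
    denom = ex.sum(axis=axis, keepdims=True)
    y = np.divide(ex, denom, out=np.zeros_like(ex), where=denom > 0)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    return _make(y, (a,), backward)


def log_softmax(logits, axis: int = -1) -> Tensor:
    a = ensure(logits)
    mx = a.data.max(axis=axis, keepdims=True)
    z = a.data - mx
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out_data = z - lse
    soft = np.exp(out_data)

    def backward(g):
        a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Standard Adam over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

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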