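"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the soft-polar-grid network needs:
broadcast arithmetic, two-operand einsum, matmul, exp/softplus/relu/sigmoid,
axis reductions (sum, max), gather by integer index, angle wrapping, and a
numerically stable sigmoid cross-entropy.  Gradients are accumulated on a
topologically sorted tape; correctness is established by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                t._parents = ()
                t._backward = None
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
                # release the subgraph eagerly: closures capture large arrays
                t._parents = ()
                t._backward = None
            else:
                # leaf: accumulate into .grad
                t.grad = g if t.grad is None else t.grad + g

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

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _binary(a, b, out_data, da, db) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    req = a.requires_grad or b.requires_grad

    def backward(g):
        out = []
        if a.requires_grad:
            out.append((a, _unbroadcast(da(g), a.data.shape)))
        if b.requires_grad:
            out.append((b, _unbroadcast(db(g), b.data.shape)))
        return out

    return Tensor(out_data, req, (a, b), backward if req else None)


def _is_scalar(x) -> bool:
    return isinstance(x, (int, float)) and not isinstance(x, bool)


def add(a, b) -> Tensor:
    if _is_scalar(b) or _is_scalar(a):
        if _is_scalar(a):
            a, b = b, a
        a = as_tensor(a)
        # python-scalar path: weak promotion preserves the array dtype
        return Tensor(a.data + b, a.requires_grad, (a,),
                      (lambda g: [(a, g)]) if a.requires_grad else None)
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def mul(a, b) -> Tensor:
    if _is_scalar(b) or _is_scalar(a):
        if _is_scalar(a):
            a, b = b, a
        a = as_tensor(a)
        return Tensor(a.data * b, a.requires_grad, (a,),
                      (lambda g: [(a, g * b)]) if a.requires_grad else None)
    a, b = as_tensor(a), as_tensor(b)
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    x = a.data
    # common exponents avoid the slow generic pow kernel
    if p == 2.0:
        out = x * x
        dfn = lambda g: g * (2.0 * x)
    elif p == -1.0:
        out = 1.0 / x
        dfn = lambda g: g * (-out * out)
    elif p == -2.0:
        out = 1.0 / (x * x)
        dfn = lambda g: g * (-2.0 * out / x)
    else:
        out = np.power(x, p)
        dfn = lambda g: g * p * np.power(x, p - 1)

    def backward(g):
        return [(a, dfn(g))]

    return Tensor(out, a.requires_grad, (a,), backward if a.requires_grad else None)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def backward(g):
        return [(a, g * out)]

    return Tensor(out, a.requires_grad, (a,), backward if a.requires_grad else None)


def softplus(a) -> Tensor:
    """log(1 + e^x), numerically stable; derivative sigmoid(x)."""
    a = as_tensor(a)
    x = a.data
    out = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        return [(a, g / (1.0 + np.exp(-x)))]

    return Tensor(out, a.requires_grad, (a,), backward if a.requires_grad else None)


def relu(a) -> Tensor:
    a = as_tensor(a)
    m = a.data > 0

    def backward(g):
        return [(a, g * m)]

    return Tensor(a.data * m, a.requires_grad, (a,), backward if a.requires_grad else None)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))

    def backward(g):
        return [(a, g * out * (1.0 - out))]

    return Tensor(out, a.requires_grad, (a,), backward if a.requires_grad else None)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _binary(
        a, b, a.data @ b.data,
        lambda g: g @ np.swapaxes(b.data, -1, -2),
        lambda g: np.swapaxes(a.data, -1, -2) @ g,
    )


def einsum(spec: str, a, b) -> Tensor:
    """Two-operand einsum.  Every input index must appear in the output or in
    the other operand (true for all contractions the model uses)."""
    a, b = as_tensor(a), as_tensor(b)
    ins, out_spec = spec.split("->")
    sa, sb = ins.split(",")

    def da(g):
        return np.einsum(f"{out_spec},{sb}->{sa}", g, b.data, optimize=True)

    def db(g):
        return np.einsum(f"{out_spec},{sa}->{sb}", g, a.data, optimize=True)

    return _binary(a, b, np.einsum(spec, a.data, b.data, optimize=True), da, db)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        if axis is None:
            return [(a, np.broadcast_to(g, a.data.shape).copy())]
        g2 = g if keepdims else np.expand_dims(g, axis)
        return [(a, np.broadcast_to(g2, a.data.shape).copy())]

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), a.requires_grad, (a,),
                  backward if a.requires_grad else None)


def tmax(a, axis: int) -> Tensor:
    """Max along one axis; gradient routed to the first argmax."""
    a = as_tensor(a)
    out = a.data.max(axis=axis)
    arg = a.data.argmax(axis=axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis)
        return [(a, ga)]

    return Tensor(out, a.requires_grad, (a,), backward if a.requires_grad else None)


def mean(a, axis=None) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        return [(a, g.reshape(a.data.shape))]

    return Tensor(a.data.reshape(shape), a.requires_grad, (a,), backward if a.requires_grad else None)


def gather(a, idx: np.ndarray) -> Tensor:
    """a[idx] for an integer index array over axis 0."""
    a = as_tensor(a)
    idx = np.asarray(idx)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return [(a, ga)]

    return Tensor(a.data[idx], a.requires_grad, (a,), backward if a.requires_grad else None)


def take(a, idx: np.ndarray) -> Tensor:
    return gather(a, idx)


def wrap_pi(a) -> Tensor:
    """Wrap values to [-pi, pi); gradient is the identity almost everywhere."""
    a = as_tensor(a)
    out = a.data - 2 * np.pi * np.floor(a.data / (2 * np.pi) + 0.5)
    out = out.astype(a.data.dtype, copy=False)

    def backward(g):
        return [(a, g)]

    return Tensor(out, a.requires_grad, (a,), backward if a.requires_grad else None)


def sigmoid_cross_entropy(logits, targets: np.ndarray) -> Tensor:
    """Elementwise stable BCE-with-logits; gradient sigmoid(z) - y."""
    z = as_tensor(logits)
    y = np.asarray(targets, dtype=z.data.dtype)
    x = z.data
    out = np.maximum(x, 0) - x * y + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        return [(z, g * (1.0 / (1.0 + np.exp(-x)) - y))]

    return Tensor(out, z.requires_grad, (z,), backward if z.requires_grad else None)


def stack(tensors: list, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in ts)

    def backward(g):
        parts = np.split(g, len(ts), axis=axis)
        return [(t, np.squeeze(p, axis=axis)) for t, p in zip(ts, parts) if t.requires_grad]

    return Tensor(np.stack([t.data for t in ts], axis=axis), req, tuple(ts),
                  backward if req else None)


class Adam:
    """Standard Adam over a list of leaf Tensors (frozen ones excluded)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype, copy=False
            )
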