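"""Minimal reverse-mode automatic differentiation on numpy arrays.

All networks in this package (encoder, MLP decoder, Point Transformer
decoder) and the differentiable image-formation model are built on the
:class:`Tensor` type defined here.  The engine is deliberately small:
dense float32 arrays, a static tape, define-by-run.  Operations needed by
the models are implemented either as compositions of elementwise
primitives or, where speed matters (neighbor gathers, the Gaussian
projection), as fused primitives with hand-written vector-Jacobian
products that are verified against finite differences in the test suite.

Conventions
-----------
* Gradients accumulate in ``Tensor.grad`` (numpy array, same shape).
* Only tensors created with ``requires_grad=True`` (parameters) or with
  at least one differentiable parent receive gradients.
* Broadcasting follows numpy; backward passes sum gradients over
  broadcast axes.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "no_grad",
    "Linear",
    "Adam",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph building (inference mode): intermediates are freed
    as soon as they go out of scope instead of being retained as
    parents, which bounds forward-pass memory."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = _GRAD_ENABLED and (
            bool(requires_grad)
            or any(p.requires_grad for p in parents)
        )
        self._parents = parents if self.requires_grad else ()
        self._vjp = vjp if self.requires_grad else None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph -----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._vjp is None:
                continue
            grads = t._vjp(t.grad)
            for p, g in zip(t._parents, grads):
                if not p.requires_grad or g is None:
                    continue
                g = _unbroadcast(np.asarray(g, dtype=np.float32), p.data.shape)
                p.grad = g if p.grad is None else p.grad + g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            vjp=lambda g: (g, g),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            vjp=lambda g: (g * other.data, g * self.data),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self.data / other.data
        return Tensor(
            out,
            parents=(self, other),
            vjp=lambda g: (g / other.data, -g * out / other.data),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out = self.data**p
        return Tensor(
            out,
            parents=(self,),
            vjp=lambda g: (g * p * self.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def vjp(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return ga, gb

        return Tensor(out, parents=(self, other), vjp=vjp)

    def __getitem__(self, key):
        out = self.data[key]

        def vjp(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return Tensor(out, parents=(self,), vjp=vjp)

    # -- elementwise -----------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), vjp=lambda g: (g * out,))

    def log(self):
        return Tensor(
            np.log(self.data), parents=(self,), vjp=lambda g: (g / self.data,)
        )

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=(self,), vjp=lambda g: (g * 0.5 / out,))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, parents=(self,), vjp=lambda g: (g * (1.0 - out * out),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, parents=(self,), vjp=lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask, parents=(self,), vjp=lambda g: (g * mask,)
        )

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape),)

        return Tensor(out, parents=(self,), vjp=vjp)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            vjp=lambda g: (g.reshape(old),),
        )

    def swapaxes(self, a, b):
        return Tensor(
            np.swapaxes(self.data, a, b),
            parents=(self,),
            vjp=lambda g: (np.swapaxes(g, a, b),),
        )

    # -- structured ops --------------------------------------------------
    def softmax(self, axis=-1):
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        out = e / e.sum(axis=axis, keepdims=True)

        def vjp(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)

        return Tensor(out, parents=(self,), vjp=vjp)

    def neighbor_gather(self, idx: np.ndarray, plan: "ScatterPlan | None" = None):
        """Gather per-point neighbor features.

        self: (..., P, C); idx: integer (P, k) → output (..., P, k, C).
        The index table is shared across leading (batch) axes.  Passing
        a precomputed :class:`ScatterPlan` makes the backward pass a
        sorted segment-sum instead of an unbuffered ``np.add.at``.
        """
        out = self.data[..., idx, :]
        n_src = self.data.shape[-2]

        def vjp(g):
            flat = g.reshape(*g.shape[:-3], -1, g.shape[-1])
            p = plan if plan is not None else ScatterPlan(idx, n_src)
            return (p.scatter(flat, self.data.shape),)

        return Tensor(out, parents=(self,), vjp=vjp)


class ScatterPlan:
    """Precomputed adjoint of a static gather: segment-sum by sort.

    For a fixed index table, the backward of ``x[..., idx, :]`` is a
    scatter-add onto the source points.  Sorting the flattened indices
    once turns that into contiguous ``np.add.reduceat`` segments, which
    is much faster than ``np.add.at``.
    """

    def __init__(self, idx: np.ndarray, n_src: int):
        flat = np.asarray(idx, dtype=np.int64).ravel()
        self.perm = np.argsort(flat, kind="stable")
        sorted_idx = flat[self.perm]
        self.targets, starts = np.unique(sorted_idx, return_index=True)
        self.starts = starts
        self.n_src = n_src

    def scatter(self, flat_grad: np.ndarray, out_shape) -> np.ndarray:
        """flat_grad: (..., P*k, C) -> accumulated (..., n_src, C)."""
        g = flat_grad[..., self.perm, :]
        seg = np.add.reduceat(g, self.starts, axis=-2)
        full = np.zeros(out_shape, dtype=flat_grad.dtype)
        full[..., self.targets, :] = seg
        return full


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def concatenate(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), vjp=vjp)


# ---------------------------------------------------------------------------
# layers & optimizer
# ---------------------------------------------------------------------------


class Linear:
    """Affine layer y = x @ W + b with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero: bool = False):
        if zero:
            w = np.zeros((n_in, n_out), dtype=np.float32)
        else:
            lim = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-lim, lim, size=(n_in, n_out)).astype(np.float32)
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


class Adam:
    """Adam with optional cosine learning-rate decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 total_steps=None):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.total_steps = total_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        if not self.total_steps:
            return self.lr
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr * 0.5 * (1.0 + np.cos(np.pi * frac))

    def step(self):
        lr = self.current_lr()
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
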