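"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable encoder (self-gated multi-branch hypergraph attention fused
with a bipartite graph convolution) needs gradients of a scalar loss with
respect to ~30 named parameter blocks.  This module provides the small set
of primitives that model requires: broadcasting arithmetic, matmul,
sigmoid / relu / softplus, a numerically stable row softmax, reductions,
row gathers and permutations.  Values are kept in float64; graphs are tiny
(a few hundred nodes), so a simple tape with topological-order backprop is
sufficient.

Gradient correctness of every primitive is enforced by finite-difference
tests; the full model gradient is additionally checked end to end.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "astensor", "add", "sub", "mul", "neg", "matmul", "transpose",
    "sigmoid", "relu", "softplus", "log", "exp", "row_softmax", "tsum",
    "tmean", "gather_rows", "permute", "stack_cols", "scale", "reshape",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value : array_like
        The forward value, stored as a float64 ndarray.
    parents : tuple
        Pairs ``(parent_tensor, vjp)`` where ``vjp`` maps the output
        cotangent to the parent's cotangent contribution.
    requires_grad : bool
        Leaf flag; non-leaf tensors inherit it from their parents.
    """

    __slots__ = ("value", "parents", "requires_grad", "grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = tuple(parents)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in parents
        )
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    @property
    def T(self):
        return transpose(self)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(astensor(other), self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(astensor(other), self)

    def backward(self):
        """Accumulate d(self)/d(leaf) into every reachable leaf's .grad."""
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node.parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.ones(())}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node.parents:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, vjp in node.parents:
                if not p.requires_grad:
                    continue
                contrib = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.value + b.value, [
        (a, lambda g: _unbroadcast(g, a.value.shape)),
        (b, lambda g: _unbroadcast(g, b.value.shape)),
    ])


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.value - b.value, [
        (a, lambda g: _unbroadcast(g, a.value.shape)),
        (b, lambda g: _unbroadcast(-g, b.value.shape)),
    ])


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.value * b.value, [
        (a, lambda g: _unbroadcast(g * b.value, a.value.shape)),
        (b, lambda g: _unbroadcast(g * a.value, b.value.shape)),
    ])


def neg(a) -> Tensor:
    a = astensor(a)
    return Tensor(-a.value, [(a, lambda g: -g)])


def scale(a, c: float) -> Tensor:
    """Multiply by a python/numpy constant (kept out of the graph)."""
    a = astensor(a)
    c = np.asarray(c, dtype=np.float64)
    return Tensor(a.value * c, [(a, lambda g: _unbroadcast(g * c, a.value.shape))])


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(a.value @ b.value, [
        (a, lambda g: g @ b.value.T),
        (b, lambda g: a.value.T @ g),
    ])


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    return Tensor(a.value.reshape(shape),
                  [(a, lambda g: np.asarray(g).reshape(a.value.shape))])


def transpose(a) -> Tensor:
    a = astensor(a)
    return Tensor(a.value.T, [(a, lambda g: g.T)])


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out = np.empty_like(a.value)
    pos = a.value >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.value[pos]))
    ez = np.exp(a.value[~pos])
    out[~pos] = ez / (1.0 + ez)
    return Tensor(out, [(a, lambda g: g * out * (1.0 - out))])


def relu(a) -> Tensor:
    a = astensor(a)
    mask = (a.value > 0).astype(np.float64)
    return Tensor(a.value * mask, [(a, lambda g: g * mask)])


def softplus(a) -> Tensor:
    """log(1 + exp(x)), stable for large |x|.  -log sigmoid(x) = softplus(-x)."""
    a = astensor(a)
    out = np.logaddexp(0.0, a.value)
    sig = 1.0 / (1.0 + np.exp(-np.clip(a.value, -500, 500)))
    return Tensor(out, [(a, lambda g: g * sig)])


def log(a) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.value), [(a, lambda g: g / a.value)])


def exp(a) -> Tensor:
    a = astensor(a)
    out = np.exp(a.value)
    return Tensor(out, [(a, lambda g: g * out)])


def row_softmax(a, mask: np.ndarray | None = None) -> Tensor:
    """Softmax along axis 1 with max-subtraction.

    With `mask` (boolean, same shape), entries where mask is False get zero
    probability; rows with an all-False mask come out uniform over all
    columns (the unmasked softmax of that row), matching the convention
    that an empty restriction imposes none.
    """
    a = astensor(a)
    x = a.value
    if mask is not None:
        use = mask.copy()
        empty = ~use.any(axis=1)
        use[empty, :] = True
        x = np.where(use, x, -np.inf)
    m = np.max(x, axis=1, keepdims=True)
    e = np.exp(x - m)
    s = e / e.sum(axis=1, keepdims=True)

    def vjp(g):
        dot = (g * s).sum(axis=1, keepdims=True)
        return s * (g - dot)

    return Tensor(s, [(a, vjp)])


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is None:
            return np.broadcast_to(g, a.value.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.value.shape).copy()

    return Tensor(out, [(a, vjp)])


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return scale(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def gather_rows(a, idx) -> Tensor:
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        out = np.zeros_like(a.value)
        np.add.at(out, idx, g)
        return out

    return Tensor(a.value[idx], [(a, vjp)])


def permute(a, row_perm, col_perm) -> Tensor:
    """Apply a row permutation then a column permutation."""
    a = astensor(a)
    row_perm = np.asarray(row_perm, dtype=np.intp)
    col_perm = np.asarray(col_perm, dtype=np.intp)
    inv_r = np.argsort(row_perm)
    inv_c = np.argsort(col_perm)
    return Tensor(a.value[row_perm][:, col_perm],
                  [(a, lambda g: g[inv_r][:, inv_c])])


def stack_cols(tensors) -> Tensor:
    """Stack 1-D tensors of length n into an n x k matrix."""
    tensors = [astensor(t) for t in tensors]
    out = np.stack([t.value for t in tensors], axis=1)
    parents = []
    for j, t in enumerate(tensors):
        parents.append((t, (lambda jj: lambda g: g[:, jj])(j)))
    return Tensor(out, parents)
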