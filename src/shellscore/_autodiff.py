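"""Compact reverse-mode automatic differentiation over NumPy arrays.

The scoring network is small (a handful of attention layers over graphs with a
few dozen nodes), so a minimal tape-based engine is sufficient: every operation
returns a :class:`Tensor` that remembers its parents and a closure accumulating
gradients into them.  All arithmetic is float64.

Only the operations the shell-graph encoder and the MLP head actually use are
implemented; each op's backward pass is covered by finite-difference tests.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "scale", "matmul", "reshape", "transpose", "concat",
    "take_row", "relu", "softplus", "softmax", "layer_norm", "gather",
    "edge_path_bias", "square", "mean_of", "AdamW",
]


class Tensor:
    """A node in the computation graph: value, gradient and backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the whole tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(-_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def scale(a, s: float) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(g * s)

    return Tensor(a.data * s, (a,), backward)


def matmul(a, b) -> Tensor:
    """Matrix product; supports stacked (batched) operands via numpy @."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.data.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return Tensor(a.data.reshape(shape), (a,), backward)


def transpose(a, axes: Sequence[int]) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return Tensor(a.data.transpose(axes), (a,), backward)


def concat(parts: Sequence[Tensor], axis: int = 0) -> Tensor:
    parts = [_as_tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accumulate(g[tuple(sl)])

    return Tensor(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), backward)


def take_row(a, i: int) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        full = np.zeros_like(a.data)
        full[i] = g
        a._accumulate(full)

    return Tensor(a.data[i], (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return Tensor(a.data * mask, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), numerically stable; maps the head output to [0, inf)."""
    a = _as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)
    sig = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * sig)

    return Tensor(out_data, (a,), backward)


def square(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(g * 2.0 * a.data)

    return Tensor(a.data ** 2, (a,), backward)


def mean_of(parts: Sequence[Tensor]) -> Tensor:
    """Mean of scalar tensors (used for the batch MSE)."""
    parts = [_as_tensor(p) for p in parts]
    n = len(parts)
    if n == 0:
        raise ValueError("mean_of() of an empty sequence")

    def backward(g):
        for p in parts:
            p._accumulate(np.full_like(p.data, float(g) / n))

    return Tensor(sum(float(p.data) for p in parts) / n, tuple(parts), backward)


def softmax(a) -> Tensor:
    """Softmax along the last axis."""
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        a._accumulate(y * (g - dot))

    return Tensor(y, (a,), backward)


def layer_norm(a, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance (no affine part)."""
    a = _as_tensor(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv

    def backward(g):
        gm = g.mean(axis=-1, keepdims=True)
        gym = (g * y).mean(axis=-1, keepdims=True)
        a._accumulate(inv * (g - gm - y * gym))

    return Tensor(y, (a,), backward)


def gather(table, idx: np.ndarray) -> Tensor:
    """Look up ``table[..., idx]`` along the last axis of ``table``.

    With ``table`` of shape (heads, S) and integer ``idx`` of shape (m, m) the
    result has shape (heads, m, m); the backward pass scatter-adds.
    """
    table = _as_tensor(table)
    idx = np.asarray(idx)
    if idx.min() < 0 or idx.max() >= table.data.shape[-1]:
        raise ValueError("gather index out of table range")
    out_data = table.data[..., idx]

    def backward(g):
        gt = np.zeros_like(table.data)
        if table.data.ndim == 2:
            flat_idx = idx.ravel()
            gflat = g.reshape(table.data.shape[0], -1)
            for h in range(table.data.shape[0]):
                np.add.at(gt[h], flat_idx, gflat[h])
        else:
            np.add.at(gt, idx.ravel(), g.reshape(-1, *g.shape[idx.ndim:]))
        table._accumulate(gt)

    return Tensor(out_data, (table,), backward)


def edge_path_bias(path_feats: np.ndarray, inv_len: np.ndarray, w_edge) -> Tensor:
    """Mean dot-product of the edge features along each shortest path.

    ``path_feats``: constant (m, m, hop_max, d_E) array, zero padded beyond each
    path's length.  ``inv_len``: constant (m, m) array holding 1/N for pairs with
    a path of length N >= 1 and 0 elsewhere.  ``w_edge``: learnable
    (heads, hop_max, d_E).  Returns the (heads, m, m) bias matrix.
    """
    w_edge = _as_tensor(w_edge)
    out_data = np.einsum("ijpe,hpe->hij", path_feats, w_edge.data) * inv_len[None]

    def backward(g):
        w_edge._accumulate(np.einsum("ijpe,hij->hpe", path_feats, g * inv_len[None]))

    return Tensor(out_data, (w_edge,), backward)


class AdamW(object):
    """AdamW with decoupled weight decay over a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * p.grad
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def numeric_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                     eps: float = 1e-6) -> np.ndarray:
    """Central finite differences; test utility for checking backward passes."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
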