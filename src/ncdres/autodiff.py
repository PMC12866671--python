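"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model graphs here are small (a few hundred nodes, a handful of dense
matrix products per layer), so a tape of :class:`Tensor` nodes over float64
numpy arrays is all that is needed.  The op set is deliberately restricted to
what the encoder/decoder require: dense matmul, elementwise add/mul with bias
broadcasting, LeakyReLU, row gather/scatter (sparse message passing), scatter
into a dense adjacency (masked dense message passing), stacked elementwise
pooling (sum/mean/max/min across relations), column concatenation, and a
numerically stabilised binary cross-entropy head.

Gradients are accumulated by a topological backward sweep from a scalar root.
Ties in max/min pooling distribute the gradient equally over the tied inputs,
which keeps the subgradient choice deterministic and symmetric.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "matmul",
    "mul",
    "scale",
    "leaky_relu",
    "concat_cols",
    "gather_rows",
    "edge_scatter",
    "scatter_dense",
    "stack_reduce",
    "sum_all",
    "bce_with_logits",
    "backward",
]


class Tensor:
    """A node in the computation tape.

    Leaf tensors (parameters, inputs under attribution) are created directly;
    interior nodes are created by the op functions below and carry a closure
    that routes the incoming gradient to their parents.
    """

    __slots__ = ("value", "grad", "parents", "_backward")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, leaf={self._backward is None})"


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value + b.value

    def bwd(g: np.ndarray) -> None:
        a._accumulate(_unbroadcast(g, a.value.shape))
        b._accumulate(_unbroadcast(g, b.value.shape))

    return Tensor(out_val, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value * b.value

    def bwd(g: np.ndarray) -> None:
        a._accumulate(_unbroadcast(g * b.value, a.value.shape))
        b._accumulate(_unbroadcast(g * a.value, b.value.shape))

    return Tensor(out_val, (a, b), bwd)


def scale(a: Tensor, c: float) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * c)

    return Tensor(a.value * c, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_val = a.value @ b.value

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g @ b.value.T)
        b._accumulate(a.value.T @ g)

    return Tensor(out_val, (a, b), bwd)


def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    mask = np.where(a.value > 0, 1.0, slope)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g * mask)

    return Tensor(a.value * mask, (a,), bwd)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    na = a.value.shape[-1]
    out_val = np.concatenate([a.value, b.value], axis=-1)

    def bwd(g: np.ndarray) -> None:
        a._accumulate(g[..., :na])
        b._accumulate(g[..., na:])

    return Tensor(out_val, (a, b), bwd)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out_val = a.value[idx]

    def bwd(g: np.ndarray) -> None:
        ga = np.zeros_like(a.value)
        np.add.at(ga, idx, g)
        a._accumulate(ga)

    return Tensor(out_val, (a,), bwd)


def edge_scatter(
    messages: Tensor,
    src: np.ndarray,
    tgt: np.ndarray,
    n_tgt: int,
    weights: Tensor | None = None,
) -> Tensor:
    """Sparse neighbour sum: ``out[t] = sum over edges e with tgt[e]==t of
    weights[e] * messages[src[e]]``.

    `weights` (one scalar per edge) is the continuous edge mask used by the
    attribution module; omitted it defaults to 1 and contributes no parent.
    """
    src = np.asarray(src, dtype=np.intp)
    tgt = np.asarray(tgt, dtype=np.intp)
    if src.shape != tgt.shape:
        raise ValueError("src and tgt index arrays must have equal length")
    if src.size and (src.max() >= messages.value.shape[0] or tgt.max() >= n_tgt):
        raise IndexError("edge index out of range")
    w = None if weights is None else weights.value
    gathered = messages.value[src]
    if w is not None:
        gathered = gathered * w[:, None]
    out_val = np.zeros((n_tgt, messages.value.shape[1]))
    np.add.at(out_val, tgt, gathered)

    parents: tuple[Tensor, ...] = (messages,) if weights is None else (messages, weights)

    def bwd(g: np.ndarray) -> None:
        g_tgt = g[tgt]
        gm = np.zeros_like(messages.value)
        np.add.at(gm, src, g_tgt if w is None else g_tgt * w[:, None])
        messages._accumulate(gm)
        if weights is not None:
            weights._accumulate(np.sum(messages.value[src] * g_tgt, axis=1))

    return Tensor(out_val, parents, bwd)


def scatter_dense(
    weights: Tensor, rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]
) -> Tensor:
    """Build a dense (n_tgt, n_src) adjacency from per-edge weights."""
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    out_val = np.zeros(shape)
    np.add.at(out_val, (rows, cols), weights.value)

    def bwd(g: np.ndarray) -> None:
        weights._accumulate(g[rows, cols])

    return Tensor(out_val, (weights,), bwd)


def stack_reduce(tensors: Sequence[Tensor], strategy: str) -> Tensor:
    """Elementwise pooling across a list of same-shape tensors."""
    if not tensors:
        raise ValueError("stack_reduce requires at least one tensor")
    shapes = {t.value.shape for t in tensors}
    if len(shapes) > 1:
        raise ValueError(f"stack_reduce shape mismatch: {sorted(shapes)}")
    stacked = np.stack([t.value for t in tensors])
    if strategy == "sum":
        out_val = stacked.sum(axis=0)
    elif strategy == "mean":
        out_val = stacked.mean(axis=0)
    elif strategy == "max":
        out_val = stacked.max(axis=0)
    elif strategy == "min":
        out_val = stacked.min(axis=0)
    else:
        raise ValueError(f"unknown aggregation strategy: {strategy!r}")

    def bwd(g: np.ndarray) -> None:
        if strategy == "sum":
            for t in tensors:
                t._accumulate(g)
        elif strategy == "mean":
            gk = g / len(tensors)
            for t in tensors:
                t._accumulate(gk)
        else:
            hit = stacked == out_val[None]
            share = hit / hit.sum(axis=0, keepdims=True)
            for t, s in zip(tensors, share):
                t._accumulate(g * s)

    return Tensor(out_val, tuple(tensors), bwd)


def sum_all(a: Tensor) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        a._accumulate(np.broadcast_to(g, a.value.shape).copy())

    return Tensor(np.asarray(a.value.sum()), (a,), bwd)


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against {0,1} labels.

    Uses the log-sum-exp form max(p,0) - p*y + log(1+exp(-|p|)), finite for
    any finite logit.
    """
    y = np.asarray(labels, dtype=np.float64)
    p = logits.value
    if p.shape != y.shape:
        raise ValueError("logits and labels must have identical shape")
    if p.size == 0:
        raise ValueError("empty input to bce_with_logits")
    per = np.maximum(p, 0.0) - p * y + np.log1p(np.exp(-np.abs(p)))
    n = p.size

    def bwd(g: np.ndarray) -> None:
        sig = 1.0 / (1.0 + np.exp(-p))
        logits._accumulate(g * (sig - y) / n)

    return Tensor(np.asarray(per.mean()), (logits,), bwd)


def backward(root: Tensor) -> None:
    """Backpropagate d(root)/d(leaf) into every `.grad` reachable from root."""
    if root.value.ndim != 0:
        raise ValueError("backward root must be a scalar tensor")
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    root.grad = np.asarray(1.0)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
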