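"""Relation-type-aware heterogeneous graph encoder.

Each undirected cross-type relation expands into two directed message streams
with independent parameters (``lm`` and ``ml``, ``ld`` and ``dl``, ``md`` and
``dm``); intra-type similarity relations keep a single parameter pair applied
symmetrically.  Per layer and per directed relation ``r`` targeting node
``v``::

    f_r(v) = h_v W_r_self + sum_{u in N_r(v)} h_u W_r_neigh

and the layer update per node type pools its three incoming streams with an
elementwise aggregation operator (min by default) followed by LeakyReLU::

    h_lncRNA = sigma( agg(f_ll, f_lm, f_ld) )
    h_miRNA  = sigma( agg(f_mm, f_ml, f_md) )
    h_drug   = sigma( agg(f_dd, f_dl, f_dm) )

There is no degree normalisation and no implicit self-loop beyond the
explicit self term.  A relation with no edges contributes its self term only.
Feature-dimension mismatch across node types is absorbed by type-specific
linear input projections before the first layer.

Two execution paths are provided: a sparse per-edge scatter path and a dense
adjacency-matrix-product reference; they must agree to numerical precision
and are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io import NcdresError
from .network import NODE_TYPES, RELATION_TYPES, HeteroNetwork

AGGREGATIONS = ("max", "mean", "sum", "min")

#: directed relation name -> (target type, source type, undirected relation)
DIRECTED_RELATIONS: dict[str, tuple[str, str, str]] = {
    "ll": ("lncRNA", "lncRNA", "ll"),
    "lm": ("lncRNA", "miRNA", "lm"),
    "ld": ("lncRNA", "drug", "ld"),
    "mm": ("miRNA", "miRNA", "mm"),
    "ml": ("miRNA", "lncRNA", "lm"),
    "md": ("miRNA", "drug", "md"),
    "dd": ("drug", "drug", "dd"),
    "dl": ("drug", "lncRNA", "ld"),
    "dm": ("drug", "miRNA", "md"),
}

#: incoming streams per node type, in the pooling order of the layer update
STREAMS_BY_TYPE: dict[str, tuple[str, str, str]] = {
    "lncRNA": ("ll", "lm", "ld"),
    "miRNA": ("mm", "ml", "md"),
    "drug": ("dd", "dl", "dm"),
}


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


@dataclass
class EncoderParams:
    """Input projections plus per-layer, per-directed-relation weight pairs.

    Matrices are stored for right multiplication: ``h W``, so ``input_proj[t]``
    has shape (feat_dim_t, hidden) and every relation weight (hidden, hidden).
    """

    input_proj: dict[str, np.ndarray]
    layers: list[dict[str, tuple[np.ndarray, np.ndarray]]]  # name -> (W_self, W_neigh)
    hidden_dim: int
    aggregation: str = "min"
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise NcdresError(f"aggregation must be one of {AGGREGATIONS}")

    @classmethod
    def init(
        cls,
        feature_dims: dict[str, int],
        hidden_dim: int = 64,
        n_layers: int = 2,
        aggregation: str = "min",
        leaky_slope: float = 0.01,
        rng: np.random.Generator | None = None,
    ) -> "EncoderParams":
        rng = rng or np.random.default_rng(0)
        proj = {
            t: _glorot(rng, max(d, 1), hidden_dim) for t, d in feature_dims.items()
        }
        layers = []
        for _ in range(n_layers):
            layer = {
                name: (
                    _glorot(rng, hidden_dim, hidden_dim),
                    _glorot(rng, hidden_dim, hidden_dim),
                )
                for name in DIRECTED_RELATIONS
            }
            layers.append(layer)
        return cls(proj, layers, hidden_dim, aggregation, leaky_slope)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def to_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for t, m in self.input_proj.items():
            out[f"proj/{t}"] = m
        for li, layer in enumerate(self.layers):
            for name, (ws, wn) in layer.items():
                out[f"layer{li}/{name}/self"] = ws
                out[f"layer{li}/{name}/neigh"] = wn
        return out

    @classmethod
    def from_arrays(
        cls,
        arrays: dict[str, np.ndarray],
        hidden_dim: int,
        aggregation: str,
        leaky_slope: float,
    ) -> "EncoderParams":
        proj = {
            k.split("/", 1)[1]: np.asarray(v)
            for k, v in arrays.items()
            if k.startswith("proj/")
        }
        n_layers = 1 + max(
            int(k[5:].split("/")[0]) for k in arrays if k.startswith("layer")
        )
        layers = []
        for li in range(n_layers):
            layers.append(
                {
                    name: (
                        np.asarray(arrays[f"layer{li}/{name}/self"]),
                        np.asarray(arrays[f"layer{li}/{name}/neigh"]),
                    )
                    for name in DIRECTED_RELATIONS
                }
            )
        return cls(proj, layers, hidden_dim, aggregation, leaky_slope)


def directed_edge_indices(
    network: HeteroNetwork, directed: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(src_idx, tgt_idx, undirected_edge_idx) arrays for a directed stream.

    Intra-type relations emit both orientations of each stored unordered
    pair; cross-type relations emit the orientation pointing at the stream's
    target type.  The third array maps each directed edge back to its
    undirected edge (used to share one attribution mask per stored edge).
    """
    tgt_type, src_type, und = DIRECTED_RELATIONS[directed]
    e = network.edges[und]
    if e.shape[0] == 0:
        z = np.zeros(0, dtype=np.intp)
        return z, z, z
    first_type, _ = RELATION_TYPES[und]
    eidx = np.arange(e.shape[0], dtype=np.intp)
    if und in ("ll", "mm", "dd"):
        src = np.concatenate([e[:, 0], e[:, 1]])
        tgt = np.concatenate([e[:, 1], e[:, 0]])
        return src, tgt, np.concatenate([eidx, eidx])
    if tgt_type == first_type:
        return e[:, 1], e[:, 0], eidx
    return e[:, 0], e[:, 1], eidx


def relation_message(
    h_src: Tensor,
    h_tgt: Tensor,
    src_idx: np.ndarray,
    tgt_idx: np.ndarray,
    w_self: Tensor,
    w_neigh: Tensor,
    mode: str = "sparse",
    edge_weights: Tensor | None = None,
) -> Tensor:
    """One directed message stream: self transform plus neighbour sum."""
    self_term = ad.matmul(h_tgt, w_self)
    n_tgt = h_tgt.value.shape[0]
    if len(src_idx) == 0 and edge_weights is None:
        return self_term
    transformed = ad.matmul(h_src, w_neigh)
    if edge_weights is None:
        edge_weights = Tensor(np.ones(len(src_idx)))
    if mode == "sparse":
        neigh = ad.edge_scatter(transformed, src_idx, tgt_idx, n_tgt, edge_weights)
    elif mode == "dense":
        adj = ad.scatter_dense(
            edge_weights, tgt_idx, src_idx, (n_tgt, h_src.value.shape[0])
        )
        neigh = ad.matmul(adj, transformed)
    else:
        raise NcdresError(f"unknown execution mode {mode!r}")
    return ad.add(self_term, neigh)


def aggregate_relations(messages: list[Tensor], strategy: str) -> Tensor:
    """Elementwise pooling of per-relation message matrices."""
    if strategy not in AGGREGATIONS:
        raise NcdresError(f"aggregation must be one of {AGGREGATIONS}")
    return ad.stack_reduce(messages, strategy)


def encoder_forward(
    network: HeteroNetwork,
    params: EncoderParams,
    mode: str = "sparse",
    features: dict[str, Tensor] | None = None,
    edge_masks: dict[str, Tensor] | None = None,
    param_tensors: dict[str, Tensor] | None = None,
) -> dict[str, Tensor]:
    """Full L-layer forward pass; returns one embedding Tensor per node type.

    `features` overrides the network's attribute matrices with (possibly
    tape-tracked) tensors, and `edge_masks` supplies one differentiable weight
    per stored undirected edge of each relation — both are the hooks used by
    the attribution module.  Without them the pass is the plain model forward.
    `param_tensors` (keyed like :meth:`EncoderParams.to_arrays`) lets the
    trainer reuse persistent leaf tensors so gradients land where it reads
    them.
    """

    def pt(key: str, arr: np.ndarray) -> Tensor:
        if param_tensors is not None and key in param_tensors:
            return param_tensors[key]
        return Tensor(arr)

    h: dict[str, Tensor] = {}
    for t in NODE_TYPES:
        n = network.n_nodes(t)
        if features is not None and t in features:
            x = features[t]
        else:
            x = Tensor(network.node_features[t])
        if n == 0:
            h[t] = Tensor(np.zeros((0, params.hidden_dim)))
            continue
        proj = pt(f"proj/{t}", params.input_proj[t])
        if x.value.shape[1] != proj.value.shape[0]:
            raise NcdresError(
                f"{t}: feature dim {x.value.shape[1]} != projection input "
                f"{proj.value.shape[0]}"
            )
        h[t] = ad.matmul(x, proj)

    directed_idx = {name: directed_edge_indices(network, name) for name in DIRECTED_RELATIONS}

    for li, layer in enumerate(params.layers):
        new_h: dict[str, Tensor] = {}
        for t in NODE_TYPES:
            if network.n_nodes(t) == 0:
                new_h[t] = h[t]
                continue
            streams = []
            for name in STREAMS_BY_TYPE[t]:
                _, src_type, und = DIRECTED_RELATIONS[name]
                src_idx, tgt_idx, eidx = directed_idx[name]
                w_self, w_neigh = layer[name]
                weights = None
                if edge_masks is not None and und in edge_masks and len(eidx):
                    weights = ad.gather_rows(edge_masks[und], eidx)
                streams.append(
                    relation_message(
                        h[src_type],
                        h[t],
                        src_idx,
                        tgt_idx,
                        pt(f"layer{li}/{name}/self", w_self),
                        pt(f"layer{li}/{name}/neigh", w_neigh),
                        mode=mode,
                        edge_weights=weights,
                    )
                )
            pooled = aggregate_relations(streams, params.aggregation)
            out = ad.leaky_relu(pooled, params.leaky_slope)
            if not np.all(np.isfinite(out.value)):
                raise NcdresError(f"non-finite embeddings at encoder layer {li}")
            new_h[t] = out
        h = new_h
    return h


def encode(network: HeteroNetwork, params: EncoderParams, mode: str = "sparse") -> dict[str, np.ndarray]:
    """Convenience wrapper returning plain arrays (no tape)."""
    return {t: v.value for t, v in encoder_forward(network, params, mode=mode).items()}
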