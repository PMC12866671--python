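"""Gradient-based attribution of predictions to features and edges.

For an explained (ncRNA, drug) pair the pre-sigmoid logit is attributed by
integrated gradients against a zero baseline: node attribute matrices are
interpolated from zero to their observed values, and every stored undirected
edge carries a continuous mask interpolated from 0 (edge absent) to 1 (edge
present).  The path integral is evaluated with a midpoint Riemann sum, whose
completeness property — attributions summing to f(x) − f(baseline) — is the
built-in correctness check.

Absolute attributions aggregated per node type and per relation give the
type-level contribution shares; the top-k edges by |attribution| form an
evidence subnetwork in which simple ncRNA→drug meta-paths are enumerated and
ranked as mechanistic hypotheses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .io import NcdresError
from .network import NODE_TYPES, RELATION_TYPES, HeteroNetwork
from .training import TASK_NCRNA_TYPE, Model

logger = logging.getLogger(__name__)


@dataclass
class AttributionResult:
    pair: tuple[str, str]
    feature_attr: dict[str, np.ndarray]  # node type -> (n_nodes, feat_dim)
    edge_attr: dict[str, np.ndarray]  # relation -> (n_edges,)
    f_input: float
    f_baseline: float
    steps: int
    trained: bool = True

    @property
    def node_type_totals(self) -> dict[str, float]:
        return {t: float(np.abs(a).sum()) for t, a in self.feature_attr.items()}

    @property
    def relation_totals(self) -> dict[str, float]:
        return {r: float(np.abs(a).sum()) for r, a in self.edge_attr.items()}

    @property
    def completeness_gap(self) -> float:
        total = sum(a.sum() for a in self.feature_attr.values()) + sum(
            a.sum() for a in self.edge_attr.values()
        )
        return float(total - (self.f_input - self.f_baseline))


def attribute_prediction(
    model: Model,
    network: HeteroNetwork,
    pair: tuple[str, str],
    steps: int = 50,
    trained: bool = True,
) -> AttributionResult:
    """Integrated-gradients attribution of one pair's logit.

    `network` should be the message-passing graph the model scores on (the
    leakage-safe training graph).  An untrained/random model is allowed but
    should be flagged via ``trained=False``; the flag is carried in the
    result metadata.
    """
    ncrna_type = TASK_NCRNA_TYPE[model.config.task]
    n_idx = np.array([network.index_of(ncrna_type, pair[0])], dtype=np.intp)
    d_idx = np.array([network.index_of("drug", pair[1])], dtype=np.intp)

    feat_types = [
        t for t in NODE_TYPES
        if network.n_nodes(t) and network.node_features[t].size
    ]
    mask_relations = [r for r in RELATION_TYPES if network.n_edges(r) > 0]
    x = {t: network.node_features[t] for t in feat_types}

    def forward(alpha: float | None) -> tuple[Tensor, dict[str, Tensor], dict[str, Tensor]]:
        a = 1.0 if alpha is None else alpha
        feats = {t: Tensor(a * x[t]) for t in feat_types}
        masks = {
            r: Tensor(np.full(network.n_edges(r), a)) for r in mask_relations
        }
        logits = model.forward_logits(
            network, n_idx, d_idx, features=feats, edge_masks=masks
        )
        return ad.sum_all(logits), feats, masks

    feat_grad = {t: np.zeros_like(x[t]) for t in feat_types}
    mask_grad = {r: np.zeros(network.n_edges(r)) for r in mask_relations}
    for i in range(steps):
        alpha = (i + 0.5) / steps
        out, feats, masks = forward(alpha)
        ad.backward(out)
        for t in feat_types:
            feat_grad[t] += feats[t].grad
        for r in mask_relations:
            mask_grad[r] += masks[r].grad

    feature_attr = {t: x[t] * feat_grad[t] / steps for t in feat_types}
    edge_attr = {r: mask_grad[r] / steps for r in mask_relations}

    f_input = float(forward(1.0)[0].value)
    f_baseline = float(forward(0.0)[0].value)
    return AttributionResult(
        pair, feature_attr, edge_attr, f_input, f_baseline, steps, trained
    )


def type_contribution_shares(
    result: AttributionResult,
) -> dict[str, dict[str, float]]:
    """Percentage of |attribution| mass per node type and per relation."""
    out: dict[str, dict[str, float]] = {}
    for name, totals in (
        ("node_types", result.node_type_totals),
        ("relations", result.relation_totals),
    ):
        mass = sum(totals.values())
        if mass == 0:
            raise NcdresError(f"all-zero attributions in category {name}")
        out[name] = {k: 100.0 * v / mass for k, v in totals.items()}
    return out


def top_k_edge_subnetwork(
    result: AttributionResult, network: HeteroNetwork, k: int = 300
) -> tuple[HeteroNetwork, dict[str, np.ndarray]]:
    """Subnetwork of the k edges with largest |attribution| (plus incident
    nodes); returns it together with the kept-edge index per relation."""
    ranked: list[tuple[float, str, int]] = []
    for r, attr in result.edge_attr.items():
        for i, a in enumerate(attr):
            ranked.append((abs(float(a)), r, i))
    if k > len(ranked):
        logger.warning("k=%d exceeds edge count %d; returning all", k, len(ranked))
    ranked.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen = ranked[:k]
    kept: dict[str, list[int]] = {r: [] for r in result.edge_attr}
    for _, r, i in chosen:
        kept[r].append(i)

    used: dict[str, set[int]] = {t: set() for t in NODE_TYPES}
    for r, idxs in kept.items():
        ta, tb = RELATION_TYPES[r]
        for i in idxs:
            a, b = network.edges[r][i]
            used[ta].add(int(a))
            used[tb].add(int(b))
    remap = {
        t: {old: new for new, old in enumerate(sorted(used[t]))} for t in NODE_TYPES
    }
    node_ids = {
        t: [network.node_ids[t][old] for old in sorted(used[t])] for t in NODE_TYPES
    }
    features = {
        t: (
            network.node_features[t][sorted(used[t])]
            if used[t]
            else np.zeros((0, 0))
        )
        for t in NODE_TYPES
    }
    edges: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray | None] = {}
    kept_idx: dict[str, np.ndarray] = {}
    for r, (ta, tb) in RELATION_TYPES.items():
        idxs = sorted(kept.get(r, []))
        kept_idx[r] = np.asarray(idxs, dtype=np.intp)
        rows = []
        for i in idxs:
            a, b = network.edges[r][i]
            na, nb = remap[ta][int(a)], remap[tb][int(b)]
            if r in ("ll", "mm", "dd") and na > nb:
                na, nb = nb, na
            rows.append((na, nb))
        edges[r] = np.asarray(rows, dtype=np.intp).reshape(-1, 2)
        scores[r] = (
            np.abs(result.edge_attr[r][idxs]) if idxs else None
        )
    return HeteroNetwork(node_ids, features, edges, scores), kept_idx


@dataclass
class MetaPath:
    nodes: list[str]
    relations: list[str]
    score: float


def _id_graph(subnetwork: HeteroNetwork) -> nx.Graph:
    g = nx.Graph()
    all_ids: list[str] = []
    for t in NODE_TYPES:
        for nid in subnetwork.node_ids[t]:
            g.add_node(nid, node_type=t)
            all_ids.append(nid)
    if len(set(all_ids)) != len(all_ids):
        raise NcdresError("node ids must be unique across types for path search")
    for r, (ta, tb) in RELATION_TYPES.items():
        sc = subnetwork.edge_scores.get(r)
        for i, (a, b) in enumerate(subnetwork.edges[r].tolist()):
            ida = subnetwork.node_ids[ta][a]
            idb = subnetwork.node_ids[tb][b]
            w = float(sc[i]) if sc is not None else 0.0
            if g.has_edge(ida, idb):
                if w > g[ida][idb]["score"]:
                    g[ida][idb].update(score=w, relation=r)
            else:
                g.add_edge(ida, idb, score=w, relation=r)
    return g


def enumerate_meta_paths(
    subnetwork: HeteroNetwork,
    source: str,
    target: str,
    max_len: int = 3,
) -> list[MetaPath]:
    """All simple source→target paths of at most `max_len` edges, ranked by
    the sum of |edge attribution| along the path (ties: lexicographic)."""
    if max_len <= 0:
        return []
    g = _id_graph(subnetwork)
    if source not in g or target not in g:
        raise NcdresError("source and target must be nodes of the subnetwork")
    paths: list[MetaPath] = []
    for nodes in nx.all_simple_paths(g, source, target, cutoff=max_len):
        rels = [g[a][b]["relation"] for a, b in zip(nodes[:-1], nodes[1:])]
        score = float(sum(g[a][b]["score"] for a, b in zip(nodes[:-1], nodes[1:])))
        paths.append(MetaPath(list(nodes), rels, score))
    paths.sort(key=lambda p: (-p.score, p.nodes))
    return paths


def export_attribution_edges(
    result: AttributionResult, network: HeteroNetwork, path
) -> None:
    """GraphML-compatible edge list: id_a, id_b, relation, attribution."""
    rows = []
    for r, (ta, tb) in RELATION_TYPES.items():
        attr = result.edge_attr.get(r)
        if attr is None:
            continue
        for i, (a, b) in enumerate(network.edges[r].tolist()):
            rows.append(
                {
                    "id_a": network.node_ids[ta][a],
                    "id_b": network.node_ids[tb][b],
                    "relation": r,
                    "attribution": float(attr[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_meta_paths(paths: list[MetaPath], path) -> None:
    pd.DataFrame(
        {
            "path": ["|".join(p.nodes) for p in paths],
            "relations": ["|".join(p.relations) for p in paths],
            "score": [p.score for p in paths],
        }
    ).to_csv(path, sep="\t", index=False)
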