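"""Construction of the six-relation heterogeneous molecular network.

Node types are lncRNA, miRNA and drug.  Intra-type similarity relations
(``ll``, ``mm``) come from Kendall tau-b rank correlation of expression
profiles across cancer cell lines, ``dd`` from Tanimoto similarity of circular
(Morgan) fingerprints; only pairs with similarity strictly greater than the
retention threshold (default 0.5) become edges.  Cross-type relations are the
curated lncRNA-miRNA interactions (``lm``) and the two prior resistance
association sets (``ld``, ``md``).

Similarity scores are stored on edges for reporting, but message passing is
unweighted: the encoder treats every retained edge alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, NcdresError, PairList, SmilesTable

logger = logging.getLogger(__name__)

NODE_TYPES = ("lncRNA", "miRNA", "drug")

#: relation -> (type of first endpoint, type of second endpoint)
RELATION_TYPES: dict[str, tuple[str, str]] = {
    "ll": ("lncRNA", "lncRNA"),
    "mm": ("miRNA", "miRNA"),
    "dd": ("drug", "drug"),
    "lm": ("lncRNA", "miRNA"),
    "ld": ("lncRNA", "drug"),
    "md": ("miRNA", "drug"),
}

INTRA_RELATIONS = ("ll", "mm", "dd")


@dataclass
class SimilarityEdgeSet:
    relation: str
    edges: list[tuple[str, str, float]]  # (id_a, id_b, score), id_a < id_b

    def __post_init__(self) -> None:
        if self.relation not in INTRA_RELATIONS:
            raise NcdresError(f"relation must be one of {INTRA_RELATIONS}")
        seen = set()
        for a, b, s in self.edges:
            if a >= b:
                raise NcdresError(f"edge ({a}, {b}) not in canonical order")
            if (a, b) in seen:
                raise NcdresError(f"duplicate edge ({a}, {b})")
            seen.add((a, b))
            if not (abs(s) <= 1.0):
                raise NcdresError(f"similarity score {s} outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class Fingerprint:
    drug_id: str
    bits: frozenset[int]
    width: int

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.width for b in self.bits):
            raise NcdresError("fingerprint bit index outside [0, width)")


@dataclass
class HeteroNetwork:
    """Typed node sets with attribute matrices and six undirected relations.

    ``edges[r]`` is an (E, 2) integer array of indices into the two endpoint
    node lists of relation ``r`` (see :data:`RELATION_TYPES`); intra-type
    relations store each unordered pair once with ``i < j``.
    """

    node_ids: dict[str, list[str]]
    node_features: dict[str, np.ndarray]
    edges: dict[str, np.ndarray]
    edge_scores: dict[str, np.ndarray | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in NODE_TYPES:
            self.node_ids.setdefault(t, [])
            self.node_features.setdefault(t, np.zeros((0, 0)))
        for r in RELATION_TYPES:
            e = self.edges.setdefault(r, np.zeros((0, 2), dtype=np.intp))
            self.edges[r] = np.asarray(e, dtype=np.intp).reshape(-1, 2)
            self.edge_scores.setdefault(r, None)
        self.validate()

    def validate(self) -> None:
        for t in NODE_TYPES:
            ids = self.node_ids[t]
            if len(set(ids)) != len(ids):
                raise NcdresError(f"duplicate node ids for type {t}")
            feats = self.node_features[t]
            if len(ids) and feats.shape[0] != len(ids):
                raise NcdresError(
                    f"{t}: feature rows {feats.shape[0]} != node count {len(ids)}"
                )
        for r, (ta, tb) in RELATION_TYPES.items():
            e = self.edges[r]
            if e.size == 0:
                continue
            if e[:, 0].min() < 0 or e[:, 0].max() >= len(self.node_ids[ta]):
                raise NcdresError(f"{r}: first endpoint index out of range")
            if e[:, 1].min() < 0 or e[:, 1].max() >= len(self.node_ids[tb]):
                raise NcdresError(f"{r}: second endpoint index out of range")
            if r in INTRA_RELATIONS:
                if np.any(e[:, 0] >= e[:, 1]):
                    raise NcdresError(f"{r}: intra-type edges must have i < j")
            key = {tuple(x) for x in e.tolist()}
            if len(key) != e.shape[0]:
                raise NcdresError(f"{r}: duplicate edges")
            scores = self.edge_scores.get(r)
            if scores is not None and len(scores) != e.shape[0]:
                raise NcdresError(f"{r}: score count != edge count")

    def n_nodes(self, node_type: str) -> int:
        return len(self.node_ids[node_type])

    def n_edges(self, relation: str) -> int:
        return int(self.edges[relation].shape[0])

    def index_of(self, node_type: str, node_id: str) -> int:
        try:
            return self.node_ids[node_type].index(node_id)
        except ValueError:
            raise NcdresError(f"{node_id!r} not a {node_type} node") from None

    def with_relation_edges(
        self, relation: str, edges: np.ndarray, scores: np.ndarray | None = None
    ) -> "HeteroNetwork":
        new_edges = dict(self.edges)
        new_edges[relation] = np.asarray(edges, dtype=np.intp).reshape(-1, 2)
        new_scores = dict(self.edge_scores)
        new_scores[relation] = scores
        return HeteroNetwork(
            {t: list(v) for t, v in self.node_ids.items()},
            {t: v.copy() for t, v in self.node_features.items()},
            new_edges,
            new_scores,
        )


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected (tau-b) Kendall rank correlation.

    Returns NaN (the no-edge sentinel) when either input has zero variance,
    where tau is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise NcdresError("kendall_tau requires two equal-length 1-D vectors")
    if x.size < 2:
        raise NcdresError("kendall_tau requires length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.debug("kendall_tau: zero-variance input, returning NaN sentinel")
        return float("nan")
    return float(stats.kendalltau(x, y).statistic)


def build_similarity_edges(
    matrix: ExpressionMatrix, threshold: float = 0.5, log_transform: bool = False
) -> SimilarityEdgeSet:
    """All unordered entity pairs with tau-b strictly above `threshold`."""
    if not (0.0 <= threshold < 1.0):
        raise NcdresError("threshold must lie in [0, 1)")
    relation = "ll" if matrix.entity_type == "lncRNA" else "mm"
    ids = matrix.entity_ids
    values = np.log1p(np.maximum(matrix.values, 0.0)) if log_transform else matrix.values
    if len(ids) < 2:
        logger.warning("fewer than 2 entities; empty similarity edge set")
        return SimilarityEdgeSet(relation, [])
    # tau-b from Spearman-free rank arithmetic is O(n^2 m log m); fine at
    # the network sizes involved (<= a few thousand entities).
    edges: list[tuple[str, str, float]] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            tau = kendall_tau(values[i], values[j])
            if np.isnan(tau):
                continue
            if tau > threshold:
                a, b = sorted((ids[i], ids[j]))
                edges.append((a, b, tau))
    return SimilarityEdgeSet(relation, edges)


def fingerprint_from_smiles(
    smiles: str, width: int = 2048, radius: int = 2
) -> Fingerprint | None:
    """Circular (Morgan) fingerprint bit set, or None if SMILES is unparsable."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        logger.warning("unparsable SMILES %r", smiles)
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    fp = gen.GetFingerprint(mol)
    return Fingerprint("", frozenset(fp.GetOnBits()), width)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A intersect B| / |A union B| over fingerprint bit sets."""
    if a.width != b.width:
        raise NcdresError("fingerprints have different widths")
    union = a.bits | b.bits
    if not union:
        logger.warning("tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    return len(a.bits & b.bits) / len(union)


def build_drug_similarity_edges(
    table: SmilesTable, threshold: float = 0.5, width: int = 2048, radius: int = 2
) -> SimilarityEdgeSet:
    fps: dict[str, Fingerprint] = {}
    for did, smi in zip(table.drug_ids, table.smiles):
        fp = fingerprint_from_smiles(smi, width=width, radius=radius)
        if fp is None:
            logger.warning("drug %s excluded from dd edges (bad SMILES)", did)
            continue
        fps[did] = replace(fp, drug_id=did)
    edges: list[tuple[str, str, float]] = []
    dids = list(fps)
    for i in range(len(dids)):
        for j in range(i + 1, len(dids)):
            s = tanimoto(fps[dids[i]], fps[dids[j]])
            if s > threshold:
                a, b = sorted((dids[i], dids[j]))
                edges.append((a, b, s))
    return SimilarityEdgeSet("dd", edges)


def encode_drug_features(
    table: SmilesTable,
    mode: str = "fingerprint",
    width: int = 2048,
    radius: int = 2,
    encoder: Callable[[list[str]], np.ndarray] | None = None,
    cache_path: str | Path | None = None,
) -> np.ndarray:
    """One feature row per drug.

    ``fingerprint`` mode returns the binary Morgan fingerprint as reals (a
    drug with unparsable SMILES gets an all-zero row).  ``pretrained-embedding``
    mode calls a pluggable external SMILES encoder (e.g. a transformer
    checkpoint) and caches the result to disk; without an encoder or a cache
    it raises, instructing fallback to fingerprint mode.
    """
    if mode == "fingerprint":
        out = np.zeros((len(table.drug_ids), width))
        for i, smi in enumerate(table.smiles):
            fp = fingerprint_from_smiles(smi, width=width, radius=radius)
            if fp is not None:
                out[i, sorted(fp.bits)] = 1.0
        return out
    if mode == "pretrained-embedding":
        if cache_path is not None and Path(cache_path).exists():
            with np.load(Path(cache_path), allow_pickle=False) as data:
                cached_ids = [s for s in data["drug_ids"]]
                if list(cached_ids) == list(table.drug_ids):
                    return np.asarray(data["embeddings"], dtype=np.float64)
        if encoder is None:
            raise NcdresError(
                "pretrained-embedding mode needs an encoder callable or a "
                "matching cache; fall back to mode='fingerprint' offline"
            )
        emb = np.asarray(encoder(list(table.smiles)), dtype=np.float64)
        if emb.shape[0] != len(table.drug_ids):
            raise NcdresError("encoder returned wrong number of rows")
        if cache_path is not None:
            np.savez(
                Path(cache_path),
                drug_ids=np.asarray(table.drug_ids),
                embeddings=emb,
            )
        return emb
    raise NcdresError(f"unknown drug feature mode {mode!r}")


def _pairs_to_indices(
    pairs: PairList,
    ids_a: list[str],
    ids_b: list[str],
    relation: str,
) -> np.ndarray:
    index_a = {v: i for i, v in enumerate(ids_a)}
    index_b = {v: i for i, v in enumerate(ids_b)}
    out = []
    dropped = 0
    seen = set()
    for a, b in pairs.pairs:
        if a in index_a and b in index_b:
            key = (index_a[a], index_b[b])
        elif b in index_a and a in index_b:
            key = (index_a[b], index_b[a])
        else:
            dropped += 1
            continue
        if key in seen:
            continue
        seen.add(key)
        out.append(key)
    if dropped:
        logger.warning("%s: dropped %d unresolvable pair(s)", relation, dropped)
    return np.asarray(out, dtype=np.intp).reshape(-1, 2)


def _similarity_to_indices(
    edge_set: SimilarityEdgeSet, ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    index = {v: i for i, v in enumerate(ids)}
    rows, scores = [], []
    for a, b, s in edge_set.edges:
        if a in index and b in index:
            i, j = sorted((index[a], index[b]))
            rows.append((i, j))
            scores.append(s)
    return (
        np.asarray(rows, dtype=np.intp).reshape(-1, 2),
        np.asarray(scores, dtype=np.float64),
    )


def assemble_network(
    lnc_expr: ExpressionMatrix,
    mi_expr: ExpressionMatrix,
    drug_table: SmilesTable,
    lm_pairs: PairList,
    ld_pairs: PairList,
    md_pairs: PairList,
    threshold: float = 0.5,
    fp_width: int = 2048,
    fp_radius: int = 2,
    drug_feature_mode: str = "fingerprint",
    drug_encoder: Callable[[list[str]], np.ndarray] | None = None,
    drop_cross_ncrna: str | None = None,
    one_hot_attributes: bool = False,
    log_transform: bool = False,
) -> HeteroNetwork:
    """Build the full six-relation network from raw inputs.

    ``drop_cross_ncrna`` ("LD" or "MD") removes the non-target ncRNA type and
    every relation touching it, leaving the three task subnetworks (ablation of
    the cross-ncRNA context).  ``one_hot_attributes`` replaces all attribute
    features with one-hot identity matrices (ablation of attribute encoding).
    """
    node_ids = {
        "lncRNA": list(lnc_expr.entity_ids),
        "miRNA": list(mi_expr.entity_ids),
        "drug": list(drug_table.drug_ids),
    }
    features = {
        "lncRNA": lnc_expr.values.copy(),
        "miRNA": mi_expr.values.copy(),
        "drug": encode_drug_features(
            drug_table, mode=drug_feature_mode, width=fp_width,
            radius=fp_radius, encoder=drug_encoder,
        ),
    }

    ll_set = build_similarity_edges(lnc_expr, threshold, log_transform)
    mm_set = build_similarity_edges(mi_expr, threshold, log_transform)
    dd_set = build_drug_similarity_edges(drug_table, threshold, fp_width, fp_radius)

    edges: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray | None] = {}
    edges["ll"], scores["ll"] = _similarity_to_indices(ll_set, node_ids["lncRNA"])
    edges["mm"], scores["mm"] = _similarity_to_indices(mm_set, node_ids["miRNA"])
    edges["dd"], scores["dd"] = _similarity_to_indices(dd_set, node_ids["drug"])
    edges["lm"] = _pairs_to_indices(lm_pairs, node_ids["lncRNA"], node_ids["miRNA"], "lm")
    edges["ld"] = _pairs_to_indices(ld_pairs, node_ids["lncRNA"], node_ids["drug"], "ld")
    edges["md"] = _pairs_to_indices(md_pairs, node_ids["miRNA"], node_ids["drug"], "md")
    scores["lm"] = scores["ld"] = scores["md"] = None

    if drop_cross_ncrna is not None:
        if drop_cross_ncrna not in ("LD", "MD"):
            raise NcdresError("drop_cross_ncrna must be 'LD' or 'MD'")
        removed = "miRNA" if drop_cross_ncrna == "LD" else "lncRNA"
        node_ids[removed] = []
        features[removed] = np.zeros((0, 0))
        for r, (ta, tb) in RELATION_TYPES.items():
            if removed in (ta, tb):
                edges[r] = np.zeros((0, 2), dtype=np.intp)
                scores[r] = None

    if one_hot_attributes:
        for t in NODE_TYPES:
            n = len(node_ids[t])
            features[t] = np.eye(n)

    if edges["ld"].shape[0] == 0 and edges["md"].shape[0] == 0:
        raise NcdresError("empty target association set")

    return HeteroNetwork(node_ids, features, edges, scores)


def save_network(network: HeteroNetwork, directory: str | Path) -> None:
    """Serialize as a directory of TSVs: nodes_{type}, features_{type},
    edges_{relation} (columns id_a, id_b, score)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in NODE_TYPES:
        pd.Series(network.node_ids[t], name="node_id").to_csv(
            directory / f"nodes_{t}.tsv", sep="\t", index=False
        )
        feats = network.node_features[t]
        pd.DataFrame(feats, index=network.node_ids[t]).to_csv(
            directory / f"features_{t}.tsv", sep="\t", header=False
        )
    for r, (ta, tb) in RELATION_TYPES.items():
        e = network.edges[r]
        ids_a = [network.node_ids[ta][i] for i in e[:, 0]]
        ids_b = [network.node_ids[tb][j] for j in e[:, 1]]
        s = network.edge_scores.get(r)
        df = pd.DataFrame(
            {"id_a": ids_a, "id_b": ids_b,
             "score": s if s is not None else np.ones(len(ids_a))}
        )
        df.to_csv(directory / f"edges_{r}.tsv", sep="\t", index=False)


def load_network(directory: str | Path) -> HeteroNetwork:
    directory = Path(directory)
    node_ids: dict[str, list[str]] = {}
    features: dict[str, np.ndarray] = {}
    for t in NODE_TYPES:
        ids = pd.read_csv(directory / f"nodes_{t}.tsv", sep="\t", dtype=str)
        node_ids[t] = [] if ids.empty else [str(v) for v in ids["node_id"]]
        fpath = directory / f"features_{t}.tsv"
        if node_ids[t]:
            feats = pd.read_csv(fpath, sep="\t", header=None, index_col=0)
            features[t] = feats.to_numpy(dtype=np.float64)
        else:
            features[t] = np.zeros((0, 0))
    edges: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray | None] = {}
    for r, (ta, tb) in RELATION_TYPES.items():
        df = pd.read_csv(directory / f"edges_{r}.tsv", sep="\t", dtype={0: str, 1: str})
        idx_a = {v: i for i, v in enumerate(node_ids[ta])}
        idx_b = {v: i for i, v in enumerate(node_ids[tb])}
        e = np.asarray(
            [[idx_a[a], idx_b[b]] for a, b in zip(df["id_a"], df["id_b"])],
            dtype=np.intp,
        ).reshape(-1, 2)
        edges[r] = e
        scores[r] = df["score"].to_numpy(dtype=np.float64) if len(df) else None
    return HeteroNetwork(node_ids, features, edges, scores)
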