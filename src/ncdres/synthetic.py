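"""Synthetic heterogeneous networks with a planted, recoverable signal.

The generator draws a nonnegative latent factor-loading vector per node and
derives everything observable from it.  Loadings model module structure the
way real molecular networks exhibit it: each node carries one dominant factor
(its co-expression module for ncRNAs, its mechanism class for drugs) on top
of faint background loadings on the remaining factors.  Node attributes are a
noisy linear map of the loadings (so attribute similarity tracks latent
similarity), similarity edges connect node pairs whose loadings correlate
above a threshold, lncRNA-miRNA interaction edges connect cross-type pairs
sharing factors, and the "true" ncRNA-drug associations are the per-drug
top-scoring latent inner products, with a configurable fraction of label
noise.  Effect sizes are set so recovery is comfortably above chance but
below ceiling (the label noise alone caps attainable ranking quality).

All randomness flows from a single seed through independent spawned
sub-streams, so every artefact is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NcdresError, PairList
from .network import NODE_TYPES, HeteroNetwork

#: study-condition defaults: 200/100/30 nodes, 8 latent factors, 5% label noise
DEFAULTS = dict(
    n_lnc=200, n_mi=100, n_drug=30, latent_dim=8, feature_dim=32,
    noise=0.05, positives_per_drug=10, similarity_threshold=0.5,
    feature_noise=0.1,
)


@dataclass
class SynthConfig:
    n_lnc: int = DEFAULTS["n_lnc"]
    n_mi: int = DEFAULTS["n_mi"]
    n_drug: int = DEFAULTS["n_drug"]
    latent_dim: int = DEFAULTS["latent_dim"]
    feature_dim: int = DEFAULTS["feature_dim"]
    noise: float = DEFAULTS["noise"]
    positives_per_drug: int = DEFAULTS["positives_per_drug"]
    similarity_threshold: float = DEFAULTS["similarity_threshold"]
    feature_noise: float = DEFAULTS["feature_noise"]
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lnc, self.n_mi, self.n_drug) < 2:
            raise NcdresError("node counts must be >= 2")
        if not (0.0 <= self.noise < 1.0):
            raise NcdresError("noise must lie in [0, 1)")
        if self.positives_per_drug > min(self.n_lnc, self.n_mi):
            raise NcdresError(
                "positives_per_drug exceeds the ncRNA count; infeasible"
            )
        if self.seed is None:
            raise NcdresError("seed is mandatory")


def _corr_edges(
    za: np.ndarray, zb: np.ndarray | None, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded Pearson correlations of latent rows.

    With `zb` None: intra-type, unordered pairs i < j.  Returns (edges,
    scores)."""

    def std_rows(z: np.ndarray) -> np.ndarray:
        c = z - z.mean(axis=1, keepdims=True)
        n = np.linalg.norm(c, axis=1, keepdims=True)
        return c / np.where(n == 0, 1.0, n)

    a = std_rows(za)
    if zb is None:
        corr = a @ a.T
        iu = np.triu_indices(len(za), k=1)
        keep = corr[iu] > threshold
        edges = np.stack([iu[0][keep], iu[1][keep]], axis=1)
        return edges.astype(np.intp), corr[iu][keep]
    b = std_rows(zb)
    corr = a @ b.T
    rows, cols = np.where(corr > threshold)
    return np.stack([rows, cols], axis=1).astype(np.intp), corr[rows, cols]


def _planted_associations(
    z_ncrna: np.ndarray,
    z_drug: np.ndarray,
    positives_per_drug: int,
    noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-drug top-p latent inner products, with a `noise` fraction of the
    labels flipped (positives dropped, unknown pairs promoted)."""
    scores = z_ncrna @ z_drug.T
    n = scores.shape[0]
    pos: set[tuple[int, int]] = set()
    for d in range(scores.shape[1]):
        cut = np.quantile(scores[:, d], 1.0 - positives_per_drug / n)
        top = np.where(scores[:, d] > cut)[0]
        # quantile cut on distinct scores leaves exactly positives_per_drug
        for i in top:
            pos.add((int(i), d))
    n_flip = int(round(noise * len(pos)))
    if n_flip:
        pos_list = sorted(pos)
        drop = rng.choice(len(pos_list), size=n_flip, replace=False)
        for i in sorted(drop, reverse=True):
            pos.discard(pos_list[i])
        universe = [
            (i, d)
            for i in range(n)
            for d in range(scores.shape[1])
            if (i, d) not in set(pos_list)
        ]
        add = rng.choice(len(universe), size=n_flip, replace=False)
        for i in add:
            pos.add(universe[i])
    return np.asarray(sorted(pos), dtype=np.intp).reshape(-1, 2)


def generate(config: SynthConfig) -> tuple[HeteroNetwork, dict[str, PairList]]:
    """Draw a synthetic network plus ground-truth association lists per task."""
    ss = np.random.SeedSequence([int(config.seed), 23])
    streams = ss.spawn(6)
    rng_z, rng_map, rng_feat, rng_ld, rng_md, _ = (
        np.random.default_rng(s) for s in streams
    )

    def loadings(n: int) -> np.ndarray:
        # faint background on all factors plus one dominant module per node
        z = 0.1 * rng_z.exponential(1.0, size=(n, config.latent_dim))
        main = rng_z.integers(0, config.latent_dim, size=n)
        z[np.arange(n), main] += 1.0 + rng_z.exponential(0.5, size=n)
        return z

    z = {
        "lncRNA": loadings(config.n_lnc),
        "miRNA": loadings(config.n_mi),
        "drug": loadings(config.n_drug),
    }
    node_ids = {
        "lncRNA": [f"LNC{i:04d}" for i in range(config.n_lnc)],
        "miRNA": [f"MIR{i:04d}" for i in range(config.n_mi)],
        "drug": [f"DRUG{i:03d}" for i in range(config.n_drug)],
    }
    features = {}
    for t in NODE_TYPES:
        p = rng_map.standard_normal((config.latent_dim, config.feature_dim))
        p /= np.sqrt(config.latent_dim)
        features[t] = z[t] @ p + config.feature_noise * rng_feat.standard_normal(
            (z[t].shape[0], config.feature_dim)
        )

    edges: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray | None] = {}
    edges["ll"], scores["ll"] = _corr_edges(z["lncRNA"], None, config.similarity_threshold)
    edges["mm"], scores["mm"] = _corr_edges(z["miRNA"], None, config.similarity_threshold)
    edges["dd"], scores["dd"] = _corr_edges(z["drug"], None, config.similarity_threshold)
    edges["lm"], scores["lm"] = _corr_edges(
        z["lncRNA"], z["miRNA"], config.similarity_threshold
    )
    edges["ld"] = _planted_associations(
        z["lncRNA"], z["drug"], config.positives_per_drug, config.noise, rng_ld
    )
    edges["md"] = _planted_associations(
        z["miRNA"], z["drug"], config.positives_per_drug, config.noise, rng_md
    )
    scores["ld"] = scores["md"] = None

    network = HeteroNetwork(node_ids, features, edges, scores)
    truth = {
        "LD": PairList(
            [
                (node_ids["lncRNA"][i], node_ids["drug"][d])
                for i, d in edges["ld"].tolist()
            ],
            "lncRNA-drug",
        ),
        "MD": PairList(
            [
                (node_ids["miRNA"][i], node_ids["drug"][d])
                for i, d in edges["md"].tolist()
            ],
            "miRNA-drug",
        ),
    }
    return network, truth


def degrade(
    network: HeteroNetwork,
    mode: str,
    seed: int = 0,
    relation: str | None = None,
) -> HeteroNetwork:
    """Apply a reproducible corruption for ablation-style control runs.

    Modes: ``shuffle_labels`` rewires the two association relations to random
    unknown pairs of the same count (destroys the planted signal while
    preserving density); ``remove_relation`` empties the named relation;
    ``randomize_features`` replaces every attribute matrix with fresh
    Gaussian noise of the same shape.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    if mode == "shuffle_labels":
        out = network
        for rel, ta, tb in (("ld", "lncRNA", "drug"), ("md", "miRNA", "drug")):
            n_a, n_b = network.n_nodes(ta), network.n_nodes(tb)
            n_e = network.n_edges(rel)
            if n_e == 0:
                continue
            flat = rng.choice(n_a * n_b, size=n_e, replace=False)
            new_edges = np.stack([flat // n_b, flat % n_b], axis=1).astype(np.intp)
            out = out.with_relation_edges(rel, new_edges)
        return out
    if mode == "remove_relation":
        if relation is None or relation not in network.edges:
            raise NcdresError("remove_relation needs a valid relation name")
        return network.with_relation_edges(
            relation, np.zeros((0, 2), dtype=np.intp)
        )
    if mode == "randomize_features":
        feats = {
            t: rng.standard_normal(network.node_features[t].shape)
            for t in network.node_ids
        }
        return HeteroNetwork(
            {t: list(v) for t, v in network.node_ids.items()},
            feats,
            {r: e.copy() for r, e in network.edges.items()},
            dict(network.edge_scores),
        )
    raise NcdresError(f"unknown degrade mode {mode!r}")
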