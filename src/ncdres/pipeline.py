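"""End-to-end helpers tying the modules together.

These are the functions the command-line interface, the examples and the
acceptance experiments call: turn a network's association relation into a
labelled dataset, train, and evaluate — optionally on degraded (control)
networks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import MetricsReport, evaluate_split
from .io import AssociationDataset, PairList
from .network import HeteroNetwork
from .synthetic import SynthConfig, degrade, generate
from .training import (
    TASK_NCRNA_TYPE,
    Model,
    TrainConfig,
    TrainHistory,
    build_dataset,
    train_model,
)


def association_pairlist(network: HeteroNetwork, task: str) -> PairList:
    """Extract the target association relation of a network as a PairList."""
    relation = "ld" if task == "LD" else "md"
    ncrna_type = TASK_NCRNA_TYPE[task]
    label = "lncRNA-drug" if task == "LD" else "miRNA-drug"
    pairs = [
        (network.node_ids[ncrna_type][i], network.node_ids["drug"][j])
        for i, j in network.edges[relation].tolist()
    ]
    return PairList(pairs, label)


def dataset_from_network(
    network: HeteroNetwork, config: TrainConfig
) -> AssociationDataset:
    positives = association_pairlist(network, config.task)
    ncrna_type = TASK_NCRNA_TYPE[config.task]
    return build_dataset(
        positives, network.node_ids[ncrna_type], network.node_ids["drug"], config
    )


def train_and_evaluate(
    network: HeteroNetwork,
    config: TrainConfig,
    k_list: tuple[int, ...] = (10, 30),
) -> tuple[Model, TrainHistory, AssociationDataset, MetricsReport]:
    """Dataset construction, training, and test-split evaluation in one call."""
    dataset = dataset_from_network(network, config)
    model, history = train_model(network, dataset, config)
    report = evaluate_split(model, network, dataset, "test", k_list)
    return model, history, dataset, report


def run_synthetic_experiment(
    synth_config: SynthConfig,
    train_config: TrainConfig,
    control: str | None = None,
    k_list: tuple[int, ...] = (10, 30),
) -> tuple[Model, TrainHistory, AssociationDataset, MetricsReport]:
    """Generate a planted-signal network and run the full pipeline on it.

    `control` optionally degrades the network first ("shuffle_labels",
    "remove_lm", "randomize_features") to produce the matched negative
    controls and ablations.
    """
    network, _ = generate(synth_config)
    if control == "shuffle_labels":
        network = degrade(network, "shuffle_labels", seed=synth_config.seed)
    elif control == "remove_lm":
        network = degrade(network, "remove_relation", relation="lm")
    elif control == "randomize_features":
        network = degrade(network, "randomize_features", seed=synth_config.seed)
    elif control is not None:
        raise ValueError(f"unknown control {control!r}")
    cfg = replace(train_config, seed=train_config.seed)
    return train_and_evaluate(network, cfg, k_list)


def planted_edge_experiment(
    seed: int,
    synth_config: SynthConfig | None = None,
    train_config: TrainConfig | None = None,
    steps: int = 50,
) -> tuple[int, int]:
    """Attribution check on a pair whose only graph signal is one lm edge.

    Trains on a planted-signal network, then rewires the graph around one
    held-out positive pair so that its ncRNA keeps exactly its strongest
    lncRNA-miRNA interaction edge (all other incident edges removed) and its
    drug is fully disconnected: the surviving lm edge is the pair's only
    signal-carrying edge.  Returns ``(rank, n_edges)`` — the 1-based rank of
    that edge when all graph edges are sorted by |attribution|.
    """
    from .interpret import attribute_prediction
    from .training import train_model, training_graph

    synth_config = synth_config or SynthConfig(seed=seed)
    train_config = train_config or TrainConfig(epochs=50, seed=seed)
    network, _ = generate(synth_config)
    dataset = dataset_from_network(network, train_config)
    model, _ = train_model(network, dataset, train_config)
    graph = training_graph(network, dataset, train_config)

    ncrna_type = TASK_NCRNA_TYPE[train_config.task]
    lm = graph.edges["lm"]
    pair = None
    for cand in dataset.positives("test"):
        if np.any(lm[:, 0] == graph.index_of(ncrna_type, cand[0])):
            pair = cand
            break
    if pair is None:
        raise ValueError("no held-out positive with an lm edge in this draw")
    ni = graph.index_of(ncrna_type, pair[0])
    di = graph.index_of("drug", pair[1])

    incident = np.where(lm[:, 0] == ni)[0]
    keep = incident[np.argmax(graph.edge_scores["lm"][incident])]

    def drop(g, rel, mask):
        sc = g.edge_scores.get(rel)
        return g.with_relation_edges(
            rel, g.edges[rel][mask], sc[mask] if sc is not None else None
        )

    g2 = graph
    e = g2.edges["lm"]
    mask = e[:, 0] != ni
    mask[keep] = True
    g2 = drop(g2, "lm", mask)
    e = g2.edges["ll"]
    g2 = drop(g2, "ll", (e[:, 0] != ni) & (e[:, 1] != ni))
    e = g2.edges["ld"]
    g2 = drop(g2, "ld", (e[:, 0] != ni) & (e[:, 1] != di))
    e = g2.edges["dd"]
    g2 = drop(g2, "dd", (e[:, 0] != di) & (e[:, 1] != di))
    e = g2.edges["md"]
    g2 = drop(g2, "md", e[:, 1] != di)

    result = attribute_prediction(model, g2, pair, steps=steps)
    planted = int(np.where(g2.edges["lm"][:, 0] == ni)[0][0])
    ranked = sorted(
        ((abs(float(a)), r, i) for r, arr in result.edge_attr.items()
         for i, a in enumerate(arr)),
        reverse=True,
    )
    rank = [(r, i) for _, r, i in ranked].index(("lm", planted)) + 1
    return rank, len(ranked)
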