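"""Ranking metrics and evaluation protocols.

AUC and AUPR come from scikit-learn (Mann-Whitney AUC with ties counted 1/2;
AUPR as the step-curve area over all score thresholds).  The top-k metrics
use binary relevance and break score ties by stable input order: candidates
are sorted on (-score, input index).

Two protocols are provided: evaluation of a frozen model on a held-out split
of the standard dataset, and the cold-start leave-one-entity-out protocol, in
which every association edge incident to one ncRNA or drug is removed before
training and the entity is then ranked against all candidate partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .io import AssociationDataset, NcdresError, PairList
from .network import HeteroNetwork
from .training import (
    TASK_NCRNA_TYPE,
    Model,
    TrainConfig,
    build_dataset,
    train_model,
    training_graph,
)

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    auc: float
    aupr: float
    precision_at_k: dict[int, float]
    recall_at_k: dict[int, float]
    ndcg_at_k: dict[int, float]
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        out: dict[str, float | int] = {
            "auc": self.auc, "aupr": self.aupr,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }
        for k, v in self.precision_at_k.items():
            out[f"precision@{k}"] = v
        for k, v in self.recall_at_k.items():
            out[f"recall@{k}"] = v
        for k, v in self.ndcg_at_k.items():
            out[f"ndcg@{k}"] = v
        return out


@dataclass
class LooResult:
    entity_id: str
    entity_type: str
    report: MetricsReport
    candidate_set_size: int


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.all(np.isin(labels, (0, 1))):
        raise NcdresError("labels must be binary")
    return labels


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative."""
    labels = _check_binary(labels)
    if len(set(labels.tolist())) < 2:
        raise NcdresError("AUC requires both classes")
    return float(roc_auc_score(labels, scores))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area of the precision-recall step curve over all thresholds."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise NcdresError("AUPR requires at least one positive")
    return float(average_precision_score(labels, scores))


def _top_k_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on (-score, input index): deterministic under ties
    return np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")


def precision_at_k(scores: np.ndarray, labels: np.ndarray, k: int) -> float:
    labels = _check_binary(labels)
    if not (1 <= k <= len(labels)):
        raise NcdresError(f"k={k} outside [1, {len(labels)}]")
    top = _top_k_order(scores)[:k]
    return float(labels[top].sum() / k)


def recall_at_k(scores: np.ndarray, labels: np.ndarray, k: int) -> float:
    labels = _check_binary(labels)
    if not (1 <= k <= len(labels)):
        raise NcdresError(f"k={k} outside [1, {len(labels)}]")
    n_pos = labels.sum()
    if n_pos == 0:
        raise NcdresError("recall@k requires at least one positive")
    top = _top_k_order(scores)[:k]
    return float(labels[top].sum() / n_pos)


def ndcg_at_k(scores: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Binary-relevance DCG over the top k, normalised by the ideal DCG."""
    labels = _check_binary(labels)
    if not (1 <= k <= len(labels)):
        raise NcdresError(f"k={k} outside [1, {len(labels)}]")
    if labels.sum() == 0:
        raise NcdresError("NDCG requires at least one positive")
    discounts = 1.0 / np.log2(np.arange(2, k + 2))
    top = _top_k_order(scores)[:k]
    dcg = float((labels[top] * discounts).sum())
    ideal = np.sort(labels)[::-1][:k]
    idcg = float((ideal * discounts).sum())
    return dcg / idcg


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, k_list: tuple[int, ...] = (10, 30)
) -> MetricsReport:
    labels = _check_binary(labels)
    usable = [k for k in k_list if 1 <= k <= len(labels)]
    skipped = set(k_list) - set(usable)
    if skipped:
        logger.warning("skipping k values beyond candidate count: %s", sorted(skipped))
    return MetricsReport(
        auc=auc(scores, labels),
        aupr=aupr(scores, labels),
        precision_at_k={k: precision_at_k(scores, labels, k) for k in usable},
        recall_at_k={k: recall_at_k(scores, labels, k) for k in usable},
        ndcg_at_k={k: ndcg_at_k(scores, labels, k) for k in usable},
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
    )


def evaluate_split(
    model: Model,
    network: HeteroNetwork,
    dataset: AssociationDataset,
    split: str = "test",
    k_list: tuple[int, ...] = (10, 30),
) -> MetricsReport:
    """Score every pair of a split with the frozen model and compute metrics.

    Scoring uses the leakage-safe graph (target relation reduced to the
    training positives), so held-out association edges never feed their own
    prediction.
    """
    recs = dataset.subset(split)
    if not recs:
        raise NcdresError(f"empty split {split!r}")
    graph = training_graph(network, dataset, model.config)
    scores = model.predict(graph, [(r.ncrna_id, r.drug_id) for r in recs])
    labels = np.array([r.label for r in recs])
    return evaluate_scores(scores, labels, k_list)


def leave_one_out(
    network: HeteroNetwork,
    associations: PairList,
    entity_id: str,
    config: TrainConfig,
    k: int = 30,
) -> LooResult:
    """Cold-start protocol for one held-out ncRNA or drug.

    All association edges incident to the entity are removed before training;
    the trained model then ranks the entity against every candidate partner
    (true partners as positives, all partners with no known association to the
    entity as negatives).
    """
    ncrna_type = TASK_NCRNA_TYPE[config.task]
    if entity_id in network.node_ids[ncrna_type]:
        side = "ncRNA"
    elif entity_id in network.node_ids["drug"]:
        side = "drug"
    else:
        raise NcdresError(f"{entity_id!r} not present in the network")

    held = [p for p in associations.pairs if entity_id in p]
    if not held:
        raise NcdresError(f"{entity_id!r} has no known associations")
    remaining = PairList(
        [p for p in associations.pairs if entity_id not in p],
        associations.relation_label,
    )
    ncrna_universe = [i for i in network.node_ids[ncrna_type] if i != entity_id]
    drug_universe = [i for i in network.node_ids["drug"] if i != entity_id]
    dataset = build_dataset(remaining, ncrna_universe, drug_universe, config)
    model, _ = train_model(network, dataset, config)
    graph = training_graph(network, dataset, config)

    if side == "ncRNA":
        partners = network.node_ids["drug"]
        pairs = [(entity_id, d) for d in partners]
        truth = {d for n, d in held if n == entity_id}
        labels = np.array([1 if d in truth else 0 for d in partners])
    else:
        partners = network.node_ids[ncrna_type]
        pairs = [(n, entity_id) for n in partners]
        truth = {n for n, d in held if d == entity_id}
        labels = np.array([1 if n in truth else 0 for n in partners])
    scores = model.predict(graph, pairs)
    report = evaluate_scores(scores, labels, (min(k, len(pairs)),))
    return LooResult(entity_id, side, report, len(pairs))


def leave_one_out_batch(
    network: HeteroNetwork,
    associations: PairList,
    entity_ids: list[str],
    config: TrainConfig,
    k: int = 30,
    out_path=None,
) -> pd.DataFrame:
    """Run the cold-start protocol per entity; one TSV row per entity."""
    rows = []
    for eid in entity_ids:
        res = leave_one_out(network, associations, eid, config, k)
        row = {"entity_id": eid, "entity_type": res.entity_type,
               "n_candidates": res.candidate_set_size}
        row.update(res.report.to_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
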