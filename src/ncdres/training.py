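"""Negative sampling, stratified splitting, and the full-graph training loop.

Negatives are drawn once, uniformly without replacement from the unknown
(ncRNA, drug) pairs, at twice the positive count by default, and held fixed
thereafter; positives and negatives are then stratified 0.6/0.2/0.2 into
train/validation/test with no pair in more than one split.

Training is full-batch Adam on the binary cross-entropy of the decoder
logits.  Before training, the target association relation in the
message-passing graph is replaced by exactly the training-split positives, so
no validation or test association edge can leak signal into the embeddings;
the same reduced graph is used when scoring held-out pairs.  A config flag
(`exclude_eval_edges=False`) restores the permissive variant for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .decoder import DecoderParams, pair_features, score_pairs_taped
from .encoder import EncoderParams, encoder_forward
from .io import (
    AssociationDataset,
    AssociationRecord,
    NcdresError,
    PairList,
    load_checkpoint,
    save_checkpoint,
)
from .network import HeteroNetwork

logger = logging.getLogger(__name__)

TASK_NCRNA_TYPE = {"LD": "lncRNA", "MD": "miRNA"}
TASK_RELATION = {"LD": "ld", "MD": "md"}


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    epochs: int = 100
    hidden_dim: int = 64
    aggregation: str = "min"
    negative_ratio: float = 2.0
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    task: str = "LD"
    n_layers: int = 2
    leaky_slope: float = 0.01
    mode: str = "sparse"
    exclude_eval_edges: bool = True
    weight_decay: float = 0.0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise NcdresError("split fractions must sum to 1")
        if self.negative_ratio < 1:
            raise NcdresError("negative_ratio must be >= 1")
        if self.epochs < 1:
            raise NcdresError("epochs must be >= 1")
        if self.task not in TASK_NCRNA_TYPE:
            raise NcdresError("task must be 'LD' or 'MD'")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    val_aupr: list[float] = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class Model:
    """A trained encoder/decoder pair plus the config that produced it."""

    encoder: EncoderParams
    decoder: DecoderParams
    config: TrainConfig

    def parameter_tensors(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in self.encoder.to_arrays().items():
            out[f"enc/{k}"] = Tensor(v)
        for k, v in self.decoder.to_arrays().items():
            out[f"dec/{k}"] = Tensor(v)
        return out

    def forward_logits(
        self,
        network: HeteroNetwork,
        ncrna_idx: np.ndarray,
        drug_idx: np.ndarray,
        param_tensors: dict[str, Tensor] | None = None,
        features: dict[str, Tensor] | None = None,
        edge_masks: dict[str, Tensor] | None = None,
        dropout_masks: dict[str, np.ndarray] | None = None,
    ) -> Tensor:
        enc_pt = dec_pt = None
        if param_tensors is not None:
            enc_pt = {k[4:]: v for k, v in param_tensors.items() if k.startswith("enc/")}
            dec_pt = {k[4:]: v for k, v in param_tensors.items() if k.startswith("dec/")}
        h = encoder_forward(
            network,
            self.encoder,
            mode=self.config.mode,
            features=features,
            edge_masks=edge_masks,
            param_tensors=enc_pt,
        )
        ncrna_type = TASK_NCRNA_TYPE[self.config.task]
        h_n, h_d = h[ncrna_type], h["drug"]
        if dropout_masks is not None:
            h_n = ad.mul(h_n, Tensor(dropout_masks[ncrna_type]))
            h_d = ad.mul(h_d, Tensor(dropout_masks["drug"]))
        joint = pair_features(
            ad.gather_rows(h_n, ncrna_idx), ad.gather_rows(h_d, drug_idx)
        )
        return score_pairs_taped(joint, self.decoder, param_tensors=dec_pt)

    def predict(
        self, network: HeteroNetwork, pairs: list[tuple[str, str]]
    ) -> np.ndarray:
        """Score (ncrna_id, drug_id) pairs on a given message-passing graph."""
        ncrna_type = TASK_NCRNA_TYPE[self.config.task]
        n_idx = np.array([network.index_of(ncrna_type, a) for a, _ in pairs], dtype=np.intp)
        d_idx = np.array([network.index_of("drug", b) for _, b in pairs], dtype=np.intp)
        return self.forward_logits(network, n_idx, d_idx).value

    def save(self, path) -> None:
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(self.config).items()
        }
        save_checkpoint(path, self.encoder.to_arrays(), self.decoder.to_arrays(), cfg)

    @classmethod
    def load(cls, path) -> "Model":
        enc_arrays, dec_arrays, cfg = load_checkpoint(path)
        cfg["split_fractions"] = tuple(cfg["split_fractions"])
        config = TrainConfig(**cfg)
        encoder = EncoderParams.from_arrays(
            enc_arrays, config.hidden_dim, config.aggregation, config.leaky_slope
        )
        decoder = DecoderParams.from_arrays(dec_arrays, config.leaky_slope)
        return cls(encoder, decoder, config)


def sample_negatives(
    positives: PairList,
    ncrna_universe: list[str],
    drug_universe: list[str],
    ratio: float = 2.0,
    seed: int = 0,
) -> PairList:
    """Uniform sample, without replacement, from the unknown pairs.

    The sample is disjoint from the positives and reproducible for a given
    seed.
    """
    pos = set(positives.pairs)
    n_needed = int(round(ratio * len(pos)))
    total = len(ncrna_universe) * len(drug_universe)
    if total - len(pos) < n_needed:
        raise NcdresError(
            f"only {total - len(pos)} unknown pairs available, need {n_needed}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    unknown = [
        (a, b) for a in ncrna_universe for b in drug_universe if (a, b) not in pos
    ]
    chosen = rng.choice(len(unknown), size=n_needed, replace=False)
    sampled = [unknown[i] for i in sorted(chosen)]
    return PairList(sampled, positives.relation_label)


def split_dataset(
    labelled_pairs: list[tuple[str, str, int]],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    task: str = "LD",
) -> AssociationDataset:
    """Stratified train/val/test split of labelled pairs.

    Split sizes per label class: floor(fraction * n) for each split, with the
    remainder assigned to train.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise NcdresError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    records: list[AssociationRecord] = []
    for label in (1, 0):
        group = [(a, b) for a, b, y in labelled_pairs if y == label]
        if not group:
            continue
        n = len(group)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        if min(n_train, n_val, n_test) < 1:
            raise NcdresError(
                f"label class {label} too small ({n}) to populate all splits"
            )
        order = rng.permutation(n)
        tags = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
        for pos_in_order, idx in enumerate(order):
            a, b = group[idx]
            records.append(AssociationRecord(a, b, label, tags[pos_in_order]))
    return AssociationDataset(records, task)


def build_dataset(
    positives: PairList,
    ncrna_universe: list[str],
    drug_universe: list[str],
    config: TrainConfig,
) -> AssociationDataset:
    """Sample negatives at the configured ratio, then split."""
    negatives = sample_negatives(
        positives, ncrna_universe, drug_universe, config.negative_ratio, config.seed
    )
    labelled = [(a, b, 1) for a, b in positives.pairs] + [
        (a, b, 0) for a, b in negatives.pairs
    ]
    return split_dataset(labelled, config.split_fractions, config.seed, config.task)


def training_graph(
    network: HeteroNetwork, dataset: AssociationDataset, config: TrainConfig
) -> HeteroNetwork:
    """Replace the target association relation by the training positives only.

    This is the leakage guard: validation/test association edges are removed
    from message passing.  With ``exclude_eval_edges=False`` all known
    positives stay in the graph (permissive variant).
    """
    relation = TASK_RELATION[config.task]
    ncrna_type = TASK_NCRNA_TYPE[config.task]
    keep = dataset.positives("train") if config.exclude_eval_edges else dataset.positives()
    idx = np.asarray(
        sorted(
            (network.index_of(ncrna_type, a), network.index_of("drug", b))
            for a, b in keep
        ),
        dtype=np.intp,
    ).reshape(-1, 2)
    graph = network.with_relation_edges(relation, idx)
    if config.exclude_eval_edges:
        _assert_no_leakage(graph, dataset, config)
    return graph


def _assert_no_leakage(
    graph: HeteroNetwork, dataset: AssociationDataset, config: TrainConfig
) -> None:
    relation = TASK_RELATION[config.task]
    ncrna_type = TASK_NCRNA_TYPE[config.task]
    in_graph = sorted(map(tuple, graph.edges[relation].tolist()))
    expected = sorted(
        (graph.index_of(ncrna_type, a), graph.index_of("drug", b))
        for a, b in dataset.positives("train")
    )
    if in_graph != expected:
        raise NcdresError(
            "leakage guard violated: message-passing target edges differ from "
            "training-split positives"
        )


class Adam:
    """Adam with the conventional default moments (0.9, 0.999)."""

    def __init__(
        self,
        tensors: dict[str, Tensor],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.tensors = tensors
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v.value) for k, v in tensors.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in tensors.items()}

    def step(self) -> None:
        self.t += 1
        for k, tensor in self.tensors.items():
            g = tensor.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * tensor.value
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            tensor.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for tensor in self.tensors.values():
            tensor.zero_grad()


def _split_indices(
    network: HeteroNetwork, dataset: AssociationDataset, config: TrainConfig, split: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ncrna_type = TASK_NCRNA_TYPE[config.task]
    recs = dataset.subset(split)
    if not recs:
        raise NcdresError(f"empty split {split!r}")
    n_idx = np.array([network.index_of(ncrna_type, r.ncrna_id) for r in recs], dtype=np.intp)
    d_idx = np.array([network.index_of("drug", r.drug_id) for r in recs], dtype=np.intp)
    y = np.array([r.label for r in recs], dtype=np.float64)
    return n_idx, d_idx, y


def train_model(
    network: HeteroNetwork,
    dataset: AssociationDataset,
    config: TrainConfig,
) -> tuple[Model, TrainHistory]:
    """Full-batch training; returns the best-validation-AUC model.

    All randomness (init, dropout) derives from ``config.seed``; two runs with
    the same inputs and seed produce identical models.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    graph = training_graph(network, dataset, config)
    ncrna_type = TASK_NCRNA_TYPE[config.task]

    ss = np.random.SeedSequence([config.seed, 11])
    init_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    feature_dims = {
        t: max(graph.node_features[t].shape[1], 1) if graph.n_nodes(t) else 1
        for t in graph.node_ids
    }
    encoder = EncoderParams.init(
        feature_dims,
        hidden_dim=config.hidden_dim,
        n_layers=config.n_layers,
        aggregation=config.aggregation,
        leaky_slope=config.leaky_slope,
        rng=init_rng,
    )
    decoder = DecoderParams.init(
        2 * config.hidden_dim, leaky_slope=config.leaky_slope, rng=init_rng
    )
    model = Model(encoder, decoder, config)
    tensors = model.parameter_tensors()
    opt = Adam(tensors, config.learning_rate, weight_decay=config.weight_decay)

    tr = _split_indices(graph, dataset, config, "train")
    va = _split_indices(graph, dataset, config, "val")

    history = TrainHistory()
    best_auc, best_arrays = -np.inf, None
    for epoch in range(config.epochs):
        opt.zero_grad()
        dropout_masks = None
        if config.dropout > 0:
            keep = 1.0 - config.dropout
            dropout_masks = {
                t: (drop_rng.uniform(size=(graph.n_nodes(t), config.hidden_dim)) < keep)
                / keep
                for t in (ncrna_type, "drug")
            }
        logits = model.forward_logits(
            graph, tr[0], tr[1], param_tensors=tensors, dropout_masks=dropout_masks
        )
        loss = ad.bce_with_logits(logits, tr[2])
        if not np.isfinite(loss.value):
            raise NcdresError(f"training diverged (non-finite loss) at epoch {epoch}")
        ad.backward(loss)
        opt.step()

        val_logits = model.forward_logits(graph, va[0], va[1], param_tensors=tensors)
        auc = float(roc_auc_score(va[2], val_logits.value))
        aupr = float(average_precision_score(va[2], val_logits.value))
        history.loss.append(float(loss.value))
        history.val_auc.append(auc)
        history.val_aupr.append(aupr)
        if auc > best_auc:
            best_auc = auc
            history.best_epoch = epoch
            best_arrays = {k: v.value.copy() for k, v in tensors.items()}

    if best_arrays is not None:
        for k, v in tensors.items():
            v.value[...] = best_arrays[k]
    return model, history
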