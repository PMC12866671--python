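import numpy as np
import pytest

from ncdres.evaluation import evaluate_split
from ncdres.pipeline import dataset_from_network
from ncdres.synthetic import SynthConfig, generate
from ncdres.training import TrainConfig, train_model


TINY_SYNTH = dict(n_lnc=60, n_mi=30, n_drug=10, positives_per_drug=8)


@pytest.fixture(scope="session")
def tiny_network():
    net, truth = generate(SynthConfig(seed=7, **TINY_SYNTH))
    return net, truth


@pytest.fixture(scope="session")
def tiny_trained():
    """A small planted network with a model trained on it (shared across
    tests that only need *some* trained model)."""
    net, _ = generate(SynthConfig(seed=7, **TINY_SYNTH))
    config = TrainConfig(epochs=50, seed=7)
    dataset = dataset_from_network(net, config)
    model, history = train_model(net, dataset, config)
    return net, dataset, model, history


def random_hetero_network(rng, n_l=6, n_m=5, n_d=4, fdim=3, p_edge=0.4):
    """Small random network with every relation populated (test helper)."""
    from ncdres.network import HeteroNetwork

    node_ids = {
        "lncRNA": [f"L{i}" for i in range(n_l)],
        "miRNA": [f"M{i}" for i in range(n_m)],
        "drug": [f"D{i}" for i in range(n_d)],
    }
    feats = {
        "lncRNA": rng.standard_normal((n_l, fdim)),
        "miRNA": rng.standard_normal((n_m, fdim)),
        "drug": rng.standard_normal((n_d, fdim)),
    }

    def intra(n):
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.uniform() < p_edge]
        return np.asarray(pairs, dtype=np.intp).reshape(-1, 2)

    def cross(na, nb):
        pairs = [(i, j) for i in range(na) for j in range(nb)
                 if rng.uniform() < p_edge]
        return np.asarray(pairs, dtype=np.intp).reshape(-1, 2)

    edges = {
        "ll": intra(n_l), "mm": intra(n_m), "dd": intra(n_d),
        "lm": cross(n_l, n_m), "ld": cross(n_l, n_d), "md": cross(n_m, n_d),
    }
    return HeteroNetwork(node_ids, feats, edges)
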