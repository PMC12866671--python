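import numpy as np
import pytest

from ncdres import autodiff as ad
from ncdres.autodiff import Tensor
from ncdres.encoder import (
    EncoderParams,
    aggregate_relations,
    encode,
    encoder_forward,
    relation_message,
)
from ncdres.io import NcdresError
from ncdres.network import HeteroNetwork

from conftest import random_hetero_network


class TestRelationMessage:
    def test_no_edges_with_identity_self_is_identity(self):
        h = Tensor(np.random.default_rng(0).standard_normal((4, 3)))
        out = relation_message(
            h, h, np.zeros(0, int), np.zeros(0, int),
            Tensor(np.eye(3)), Tensor(np.eye(3)),
        )
        np.testing.assert_allclose(out.value, h.value)

    def test_single_directed_edge_routes_source_embedding(self):
        h = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = relation_message(
            h, h, np.array([0]), np.array([1]),
            Tensor(np.zeros((2, 2))), Tensor(np.eye(2)),
        )
        np.testing.assert_allclose(out.value[1], [1.0, 2.0])
        np.testing.assert_allclose(out.value[0], [0.0, 0.0])

    def test_star_graph_sums_neighbours(self):
        # centre is target node 0 of a 4-node type; 3 neighbours
        h = Tensor(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))
        out = relation_message(
            h, h, np.array([1, 2, 3]), np.array([0, 0, 0]),
            Tensor(np.zeros((2, 2))), Tensor(np.eye(2)),
        )
        np.testing.assert_allclose(out.value[0], [2.0, 2.0])

    def test_out_of_range_edge_index_is_error(self):
        h = Tensor(np.zeros((2, 2)))
        with pytest.raises(IndexError):
            relation_message(
                h, h, np.array([5]), np.array([0]),
                Tensor(np.eye(2)), Tensor(np.eye(2)),
            )


class TestAggregateRelations:
    def test_mean_of_identical_matrices_is_identity(self):
        m = np.random.default_rng(1).standard_normal((3, 2))
        out = aggregate_relations([Tensor(m)] * 3, "mean")
        np.testing.assert_allclose(out.value, m)

    def test_scalar_examples_all_strategies(self):
        a, b = Tensor(np.array([[1.0]])), Tensor(np.array([[3.0]]))
        assert aggregate_relations([a, b], "sum").value[0, 0] == 4.0
        assert aggregate_relations([a, b], "min").value[0, 0] == 1.0
        assert aggregate_relations([a, b], "max").value[0, 0] == 3.0

    @pytest.mark.parametrize("strategy", ["max", "mean", "sum", "min"])
    def test_matches_elementwise_brute_force(self, strategy):
        rng = np.random.default_rng(2)
        mats = [rng.standard_normal((4, 2)) for _ in range(3)]
        out = aggregate_relations([Tensor(m) for m in mats], strategy).value
        for i in range(4):
            for j in range(2):
                vals = [m[i, j] for m in mats]
                want = {
                    "max": max(vals), "min": min(vals),
                    "sum": sum(vals), "mean": sum(vals) / 3,
                }[strategy]
                assert out[i, j] == pytest.approx(want)

    def test_shape_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            aggregate_relations(
                [Tensor(np.zeros((2, 2))), Tensor(np.zeros((3, 2)))], "sum"
            )


def make_params(net, hidden=8, n_layers=2, aggregation="sum", seed=0):
    dims = {t: max(net.node_features[t].shape[1], 1) for t in net.node_ids}
    return EncoderParams.init(
        dims, hidden, n_layers, aggregation, rng=np.random.default_rng(seed)
    )


class TestEncoderForward:
    @pytest.mark.parametrize("aggregation", ["max", "mean", "sum", "min"])
    def test_sparse_equals_dense_reference(self, aggregation):
        rng = np.random.default_rng(3)
        for _ in range(10):
            net = random_hetero_network(rng)
            params = make_params(net, aggregation=aggregation, seed=int(rng.integers(1e6)))
            hs = encode(net, params, mode="sparse")
            hd = encode(net, params, mode="dense")
            for t in hs:
                np.testing.assert_allclose(hs[t], hd[t], rtol=1e-5, atol=1e-10)

    def test_zero_edge_network_gives_equal_outputs_for_equal_features(self):
        node_ids = {"lncRNA": ["a", "b"], "miRNA": ["m"], "drug": ["d"]}
        feats = {
            "lncRNA": np.array([[1.0, 2.0], [1.0, 2.0]]),
            "miRNA": np.array([[0.5, 0.5]]),
            "drug": np.array([[1.0, 0.0]]),
        }
        net = HeteroNetwork(node_ids, feats, {})
        h = encode(net, make_params(net))
        np.testing.assert_allclose(h["lncRNA"][0], h["lncRNA"][1])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            net = random_hetero_network(rng, n_l=5, n_m=4, n_d=3)
            params = make_params(net, aggregation="min", seed=trial)
            base = encode(net, params)

            perms = {t: rng.permutation(len(net.node_ids[t])) for t in net.node_ids}
            inv = {t: np.argsort(p) for t, p in perms.items()}
            from ncdres.network import RELATION_TYPES

            new_edges = {}
            for r, (ta, tb) in RELATION_TYPES.items():
                e = net.edges[r].copy()
                if e.size:
                    e = np.stack([inv[ta][e[:, 0]], inv[tb][e[:, 1]]], axis=1)
                    if r in ("ll", "mm", "dd"):
                        e = np.sort(e, axis=1)
                new_edges[r] = e
            pnet = HeteroNetwork(
                {t: [net.node_ids[t][i] for i in perms[t]] for t in net.node_ids},
                {t: net.node_features[t][perms[t]] for t in net.node_ids},
                new_edges,
            )
            permuted = encode(pnet, params)
            for t in base:
                np.testing.assert_allclose(
                    permuted[t], base[t][perms[t]], rtol=1e-8, atol=1e-10
                )

    def test_hand_computed_single_layer_sum_forward(self):
        # 2 lncRNAs, 1 miRNA, 1 drug; identity-like weights, sum aggregation
        node_ids = {"lncRNA": ["a", "b"], "miRNA": ["m"], "drug": ["d"]}
        feats = {
            "lncRNA": np.array([[1.0, 0.0], [0.0, 1.0]]),
            "miRNA": np.array([[1.0, 1.0]]),
            "drug": np.array([[2.0, 0.0]]),
        }
        edges = {
            "ll": np.array([[0, 1]]),
            "lm": np.array([[0, 0]]),
            "ld": np.array([[1, 0]]),
        }
        net = HeteroNetwork(node_ids, feats, edges)
        eye = np.eye(2)
        params = EncoderParams(
            input_proj={t: eye.copy() for t in node_ids},
            layers=[{name: (eye.copy(), eye.copy())
                     for name in ("ll", "lm", "ld", "mm", "ml", "md", "dd", "dl", "dm")}],
            hidden_dim=2,
            aggregation="sum",
            leaky_slope=0.01,
        )
        h = encode(net, params)
        # f_ll(a)=a+b, f_lm(a)=a+m, f_ld(a)=a -> 3a+b+m = (4,2)
        np.testing.assert_allclose(h["lncRNA"][0], [4.0, 2.0])
        # b: f_ll=b+a, f_lm=b, f_ld=b+d -> 3b+a+d = (3,3)
        np.testing.assert_allclose(h["lncRNA"][1], [3.0, 3.0])
        # m: f_mm=m, f_ml=m+a, f_md=m -> 3m+a = (4,3)
        np.testing.assert_allclose(h["miRNA"][0], [4.0, 3.0])
        # d: f_dd=d, f_dl=d+b, f_dm=d -> 3d+b = (6,1)
        np.testing.assert_allclose(h["drug"][0], [6.0, 1.0])

    def test_relation_locality_under_sum(self):
        rng = np.random.default_rng(5)
        net = random_hetero_network(rng)
        params = make_params(net, n_layers=1, aggregation="sum")
        full = encode(net, params)
        cut = net.with_relation_edges("lm", np.zeros((0, 2), int))
        reduced = encode(cut, params)
        # only lncRNA and miRNA outputs may change when lm is deleted
        np.testing.assert_allclose(full["drug"], reduced["drug"])
        assert not np.allclose(full["lncRNA"], reduced["lncRNA"])

    def test_every_parameter_receives_gradient(self):
        rng = np.random.default_rng(6)
        net = random_hetero_network(rng, p_edge=0.7)
        params = make_params(net, aggregation="mean")
        tensors = {k: Tensor(v) for k, v in params.to_arrays().items()}
        h = encoder_forward(net, params, param_tensors=tensors)
        total = ad.sum_all(
            ad.add(ad.sum_all(h["lncRNA"]),
                   ad.add(ad.sum_all(h["miRNA"]), ad.sum_all(h["drug"])))
        )
        ad.backward(total)
        for name, t in tensors.items():
            assert t.grad is not None and np.any(t.grad != 0), name

    def test_nan_in_forward_names_the_layer(self):
        rng = np.random.default_rng(7)
        net = random_hetero_network(rng)
        params = make_params(net)
        params.layers[1]["ll"][0][0, 0] = np.nan
        with pytest.raises(NcdresError, match="layer 1"):
            encode(net, params)
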