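import itertools

import numpy as np
import pytest

from ncdres.io import ExpressionMatrix, NcdresError, PairList, SmilesTable
from ncdres.network import (
    Fingerprint,
    assemble_network,
    build_similarity_edges,
    encode_drug_features,
    fingerprint_from_smiles,
    kendall_tau,
    load_network,
    save_network,
    tanimoto,
)


def tau_b_oracle(x, y):
    """Brute-force tie-corrected Kendall tau over all index pairs."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    # tau-b: (C - D) / sqrt((n0 - Tx)(n0 - Ty)) with Tx, Ty pairs tied in x, y
    n_tx = sum(1 for i, j in itertools.combinations(range(n), 2) if x[i] == x[j])
    n_ty = sum(1 for i, j in itertools.combinations(range(n), 2) if y[i] == y[j])
    return (conc - disc) / np.sqrt((n0 - n_tx) * (n0 - n_ty))


class TestKendallTau:
    def test_perfect_concordance(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert kendall_tau([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_single_swap_matches_pair_counting(self):
        # 6 index pairs, 5 concordant, 1 discordant -> 4/6
        assert kendall_tau([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(4 / 6)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.integers(0, 4, size=8).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert kendall_tau(x, y) == pytest.approx(tau_b_oracle(x, y), abs=1e-12)

    def test_symmetry_and_bounds_on_random_input(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x, y = rng.standard_normal(10), rng.standard_normal(10)
            t = kendall_tau(x, y)
            assert t == pytest.approx(kendall_tau(y, x))
            assert abs(t) <= 1.0

    def test_zero_variance_returns_nan_sentinel(self):
        assert np.isnan(kendall_tau([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(NcdresError):
            kendall_tau([1, 2], [1, 2, 3])


class TestSimilarityEdges:
    def matrix(self, rows, ids=None, entity_type="lncRNA"):
        ids = ids or [f"E{i}" for i in range(len(rows))]
        return ExpressionMatrix(ids, np.asarray(rows, float), entity_type)

    def test_identical_rows_fully_connected_at_score_one(self):
        es = build_similarity_edges(self.matrix([[1, 2, 3]] * 3))
        assert len(es) == 3
        assert all(s == pytest.approx(1.0) for _, _, s in es.edges)

    def test_anticorrelated_pairs_excluded(self):
        es = build_similarity_edges(
            self.matrix([[1, 2, 3], [3, 2, 1], [1, 2, 3]])
        )
        assert [(a, b) for a, b, _ in es.edges] == [("E0", "E2")]

    def test_equals_exhaustive_brute_force(self):
        rng = np.random.default_rng(3)
        m = self.matrix(rng.standard_normal((10, 6)).round(1).tolist())
        es = build_similarity_edges(m, threshold=0.3)
        expected = set()
        for i, j in itertools.combinations(range(10), 2):
            t = tau_b_oracle(m.values[i], m.values[j])
            if t > 0.3:
                expected.add(tuple(sorted((m.entity_ids[i], m.entity_ids[j]))))
        assert {(a, b) for a, b, _ in es.edges} == expected

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(4)
        m = self.matrix(rng.standard_normal((8, 5)).tolist())
        lo = {(a, b) for a, b, _ in build_similarity_edges(m, 0.2).edges}
        hi = {(a, b) for a, b, _ in build_similarity_edges(m, 0.6).edges}
        assert hi <= lo

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        rows = rng.standard_normal((7, 5)).tolist()
        ids = [f"E{i}" for i in range(7)]
        perm = rng.permutation(7)
        a = build_similarity_edges(self.matrix(rows, ids), 0.2)
        b = build_similarity_edges(
            self.matrix([rows[i] for i in perm], [ids[i] for i in perm]), 0.2
        )
        assert {(x, y) for x, y, _ in a.edges} == {(x, y) for x, y, _ in b.edges}

    def test_single_entity_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            es = build_similarity_edges(self.matrix([[1, 2, 3]]))
        assert len(es) == 0


class TestFingerprints:
    def test_deterministic_for_same_smiles(self):
        a = fingerprint_from_smiles("CCO")
        b = fingerprint_from_smiles("CCO")
        assert a.bits == b.bits and len(a.bits) > 0

    def test_methane_has_nonempty_bit_set(self):
        assert len(fingerprint_from_smiles("C").bits) > 0

    def test_canonical_and_noncanonical_smiles_agree(self):
        from rdkit import Chem

        canonical = Chem.MolToSmiles(Chem.MolFromSmiles("OCC"))
        assert fingerprint_from_smiles("OCC").bits == fingerprint_from_smiles(
            canonical
        ).bits

    def test_unparsable_smiles_returns_none(self):
        assert fingerprint_from_smiles("not-a-molecule") is None

    def test_tanimoto_identity_disjoint_and_half(self):
        fp = lambda bits: Fingerprint("x", frozenset(bits), 16)
        assert tanimoto(fp({1, 2, 3}), fp({1, 2, 3})) == 1.0
        assert tanimoto(fp({1, 2}), fp({3, 4})) == 0.0
        assert tanimoto(fp({1, 2, 3}), fp({2, 3, 4})) == 0.5

    def test_tanimoto_both_empty_defined_as_zero(self):
        fp = lambda bits: Fingerprint("x", frozenset(bits), 16)
        assert tanimoto(fp(set()), fp(set())) == 0.0

    def test_tanimoto_width_mismatch_is_error(self):
        with pytest.raises(NcdresError):
            tanimoto(
                Fingerprint("a", frozenset({1}), 16),
                Fingerprint("b", frozenset({1}), 32),
            )


class TestDrugFeatures:
    table = SmilesTable(["D1", "D2", "D3"], ["CCO", "CCO", "c1ccccc1"])

    def test_fingerprint_mode_shape_and_binary_range(self):
        x = encode_drug_features(self.table, width=512)
        assert x.shape == (3, 512)
        assert set(np.unique(x)) <= {0.0, 1.0}

    def test_identical_smiles_identical_rows(self):
        x = encode_drug_features(self.table, width=512)
        np.testing.assert_array_equal(x[0], x[1])
        assert not np.array_equal(x[0], x[2])

    def test_pretrained_mode_without_encoder_is_hard_error(self):
        with pytest.raises(NcdresError, match="fingerprint"):
            encode_drug_features(self.table, mode="pretrained-embedding")

    def test_pretrained_cache_round_trip(self, tmp_path):
        calls = []

        def enc(smiles):
            calls.append(1)
            return np.arange(len(smiles) * 4, dtype=float).reshape(len(smiles), 4)

        cache = tmp_path / "emb.npz"
        x1 = encode_drug_features(
            self.table, mode="pretrained-embedding", encoder=enc, cache_path=cache
        )
        x2 = encode_drug_features(
            self.table, mode="pretrained-embedding", encoder=None, cache_path=cache
        )
        np.testing.assert_array_equal(x1, x2)
        assert len(calls) == 1


class TestAssembleNetwork:
    def inputs(self):
        rng = np.random.default_rng(6)
        lnc = ExpressionMatrix(
            [f"L{i}" for i in range(5)], rng.standard_normal((5, 6)), "lncRNA"
        )
        mi = ExpressionMatrix(
            [f"M{i}" for i in range(5)], rng.standard_normal((5, 6)), "miRNA"
        )
        drugs = SmilesTable(["D0", "D1", "D2"], ["CCO", "c1ccccc1", "CC(=O)O"])
        lm = PairList([("L0", "M1"), ("L2", "M0")], "lncRNA-miRNA")
        ld = PairList([("L0", "D0"), ("L3", "D2")], "lncRNA-drug")
        md = PairList([("M0", "D1"), ("M4", "D2")], "miRNA-drug")
        return lnc, mi, drugs, lm, ld, md

    def test_synthetic_inputs_build_valid_network(self):
        net = assemble_network(*self.inputs(), fp_width=256)
        net.validate()
        assert net.n_nodes("lncRNA") == 5 and net.n_nodes("drug") == 3
        assert net.n_edges("ld") == 2 and net.n_edges("md") == 2

    def test_unresolvable_pairs_dropped_with_count(self, caplog):
        lnc, mi, drugs, lm, ld, md = self.inputs()
        ld = PairList(ld.pairs + [("L9", "D0")], "lncRNA-drug")
        with caplog.at_level("WARNING"):
            net = assemble_network(lnc, mi, drugs, lm, ld, md, fp_width=256)
        assert net.n_edges("ld") == 2
        assert "dropped 1" in caplog.text

    def test_drop_cross_ncrna_removes_other_type_and_relations(self):
        net = assemble_network(*self.inputs(), fp_width=256, drop_cross_ncrna="LD")
        assert net.n_nodes("miRNA") == 0
        assert net.n_edges("lm") == net.n_edges("mm") == net.n_edges("md") == 0
        assert net.n_edges("ld") == 2

    def test_one_hot_attributes_replace_features(self):
        net = assemble_network(*self.inputs(), fp_width=256, one_hot_attributes=True)
        for t in ("lncRNA", "miRNA", "drug"):
            np.testing.assert_array_equal(
                net.node_features[t], np.eye(net.n_nodes(t))
            )

    def test_empty_target_association_set_is_hard_error(self):
        lnc, mi, drugs, lm, ld, md = self.inputs()
        empty_ld = PairList([], "lncRNA-drug")
        empty_md = PairList([], "miRNA-drug")
        with pytest.raises(NcdresError, match="empty target"):
            assemble_network(lnc, mi, drugs, lm, empty_ld, empty_md, fp_width=256)

    def test_directory_round_trip(self, tmp_path):
        net = assemble_network(*self.inputs(), fp_width=256)
        save_network(net, tmp_path / "net")
        back = load_network(tmp_path / "net")
        assert back.node_ids == net.node_ids
        for t in net.node_ids:
            np.testing.assert_allclose(
                back.node_features[t], net.node_features[t], atol=1e-12
            )
        for r in net.edges:
            np.testing.assert_array_equal(back.edges[r], net.edges[r])
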