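"""Metapath enumeration and HeteSim relevance scores."""

import numpy as np
import pytest

from hetlink import (
    EdgeSet,
    LNCRNA,
    MetaPath,
    NodeRegistry,
    PROTEIN,
    build_hetnet,
    enumerate_metapaths,
    hetesim_features,
    hetesim_matrix,
    hetesim_score,
    normalize_rows,
    reachability,
)
from hetlink.hetnet import SchemaError

from conftest import random_typed_net
from oracles import hetesim_enumeration

CATALOGUE = [
    "PLL", "PPL",
    "PPLL", "PLPL", "PLLL", "PPPL",
    "PPPPL", "PLPPL", "PPLPL", "PLLPL", "PPPLL", "PLPLL", "PPLLL", "PLLLL",
]


class TestEnumeration:
    def test_full_catalogue_names_and_order(self):
        assert [p.name for p in enumerate_metapaths(3, 5)] == CATALOGUE

    def test_three_node_paths(self):
        assert [p.name for p in enumerate_metapaths(3, 3)] == ["PLL", "PPL"]

    def test_direct_edge_only(self):
        assert [p.name for p in enumerate_metapaths(2, 2)] == ["PL"]

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6, 7])
    def test_counting_identity(self, k):
        # admissible strings of node count k: 2^(k-2)
        assert len(enumerate_metapaths(k, k)) == 2 ** (k - 2)

    def test_malformed_names_rejected(self):
        for bad in ("LP", "PP", "P", "PXL"):
            with pytest.raises(ValueError):
                MetaPath(bad)


class TestNormalizeRows:
    def test_simple_row(self):
        out = normalize_rows(np.array([[1.0, 1.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.5, 0.5, 0.0]])

    def test_zero_row_stays_zero(self):
        out = normalize_rows(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(out, [[0, 0], [0.5, 0.5]])

    def test_random_nonzero_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        A = rng.random((4, 3))
        sums = normalize_rows(A).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_rows(np.array([[-1.0, 2.0]]))


class TestReachability:
    def test_direct_relation_is_normalized_adjacency(self, toy_net):
        R = reachability(MetaPath("PL"), toy_net).R
        # p0 splits mass between p1 and l0 is not relevant here: the PL
        # block only sees lncRNA columns; p0-l0 and p1-l0 each have one
        # PL neighbor
        np.testing.assert_allclose(R, [[1.0, 0.0], [1.0, 0.0]])

    def test_hand_multiplied_two_step_product(self, toy_net):
        # PPL: row-normalized PP block times row-normalized PL block
        R = reachability(MetaPath("PPL"), toy_net).R
        expected = np.array([[0, 1.0], [1.0, 0]]) @ np.array([[1.0, 0], [1.0, 0]])
        np.testing.assert_allclose(R, expected)

    def test_permutation_blocks_give_permutation_product(self):
        # PL block is a perfect matching p_i - l_i, LL a matching l0-l1
        registry = NodeRegistry(
            ["p0", "p1", "l0", "l1"],
            {"p0": PROTEIN, "p1": PROTEIN, "l0": LNCRNA, "l1": LNCRNA},
        )
        pl = EdgeSet("PL", [("p0", "l0"), ("p1", "l1")], np.ones(2))
        ll = EdgeSet("LL", [("l0", "l1")], np.ones(1))
        net = build_hetnet(
            [EdgeSet("PP", [], np.array([])), ll, pl], registry=registry
        )
        R = reachability(MetaPath("PLL"), net).R
        np.testing.assert_allclose(R, [[0, 1.0], [1.0, 0]])
        assert np.all((R == 0) | (R == 1))

    def test_row_sums_never_exceed_one(self, small_truth):
        for path in enumerate_metapaths(3, 5):
            R = reachability(path, small_truth.net).R
            assert R.min() >= 0
            assert R.max() <= 1 + 1e-9
            assert R.sum(axis=1).max() <= 1 + 1e-9


class TestHeteSimScore:
    def test_disconnected_pair_scores_zero(self):
        registry = NodeRegistry(
            ["p0", "p1", "l0", "l1"],
            {"p0": PROTEIN, "p1": PROTEIN, "l0": LNCRNA, "l1": LNCRNA},
        )
        pl = EdgeSet("PL", [("p1", "l1")], np.ones(1))
        net = build_hetnet(
            [EdgeSet("PP", [], np.array([])),
             EdgeSet("LL", [], np.array([])), pl],
            registry=registry,
        )
        for path in enumerate_metapaths(3, 5):
            assert hetesim_score(path, "p0", "l0", net) == 0.0

    def test_identical_reachability_rows_score_one(self):
        # p0 and p1 both connect only to l0; along PPL... use PLL where
        # both walkers land on the same single midpoint lncRNA
        registry = NodeRegistry(
            ["p0", "l0", "l1"],
            {"p0": PROTEIN, "l0": LNCRNA, "l1": LNCRNA},
        )
        pl = EdgeSet("PL", [("p0", "l0")], np.ones(1))
        ll = EdgeSet("LL", [("l0", "l1")], np.ones(1))
        net = build_hetnet(
            [EdgeSet("PP", [], np.array([])), ll, pl], registry=registry
        )
        assert hetesim_score(MetaPath("PLL"), "p0", "l1", net) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = np.random.default_rng(77)
        paths = enumerate_metapaths(3, 5)
        for _ in range(8):
            net = random_typed_net(rng, int(rng.integers(3, 8)),
                                   int(rng.integers(3, 8)))
            prots = [net.registry.ids[k] for k in net.protein_indices()]
            lncs = [net.registry.ids[k] for k in net.lncrna_indices()]
            p = prots[int(rng.integers(len(prots)))]
            l = lncs[int(rng.integers(len(lncs)))]
            for path in paths:
                got = hetesim_score(path, p, l, net)
                want = hetesim_enumeration(net, path.name, p, l)
                assert got == pytest.approx(want, abs=1e-10), path.name

    def test_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(13)
        net = random_typed_net(rng, 5, 5)
        # rebuild the same topology with permuted identifiers
        perm_p = {f"p{i}": f"p{j}" for i, j in
                  enumerate(rng.permutation(5).tolist())}
        perm_l = {f"l{i}": f"l{j}" for i, j in
                  enumerate(rng.permutation(5).tolist())}
        relabel = {**perm_p, **perm_l}
        sets = []
        for cls in ("PP", "LL", "PL"):
            es = net.edges[cls]
            sets.append(EdgeSet(cls, [(relabel[a], relabel[b])
                                      for a, b in es.pairs], es.weights))
        registry = NodeRegistry(
            list(net.registry.ids),
            dict(net.registry.node_type),
        )
        net2 = build_hetnet(sets, registry=registry, threshold=0.0)
        for path in enumerate_metapaths(3, 5):
            s1 = hetesim_score(path, "p0", "l0", net)
            s2 = hetesim_score(path, relabel["p0"], relabel["l0"], net2)
            assert s1 == pytest.approx(s2, abs=1e-12)

    def test_scores_within_unit_interval(self, small_truth):
        for path in enumerate_metapaths(3, 5):
            M = hetesim_matrix(path, small_truth.net)
            assert M.min() >= 0.0
            assert M.max() <= 1.0

    def test_type_mismatch_rejected(self, toy_net):
        with pytest.raises(SchemaError):
            hetesim_score(MetaPath("PLL"), "l0", "l1", toy_net)


class TestHeteSimFeatures:
    def test_vector_length_and_order(self, toy_net):
        feats = hetesim_features([("p0", "l0")], toy_net)
        assert feats.scores.shape == (1, 14)
        assert feats.path_names == CATALOGUE

    def test_empty_pl_layer_zeroes_pl_dependent_paths(self):
        registry = NodeRegistry(
            ["p0", "p1", "l0", "l1"],
            {"p0": PROTEIN, "p1": PROTEIN, "l0": LNCRNA, "l1": LNCRNA},
        )
        pp = EdgeSet("PP", [("p0", "p1")], np.ones(1))
        ll = EdgeSet("LL", [("l0", "l1")], np.ones(1))
        net = build_hetnet(
            [pp, ll, EdgeSet("PL", [], np.array([]))], registry=registry
        )
        feats = hetesim_features([("p0", "l0")], net)
        # every catalogued path crosses the PL relation at least once
        assert np.all(feats.scores == 0.0)

    def test_masking_own_edge_removes_sole_connection(self):
        registry = NodeRegistry(
            ["p0", "l0"], {"p0": PROTEIN, "l0": LNCRNA}
        )
        pl = EdgeSet("PL", [("p0", "l0")], np.ones(1))
        net = build_hetnet(
            [EdgeSet("PP", [], np.array([])),
             EdgeSet("LL", [], np.array([])), pl],
            registry=registry,
        )
        unmasked = hetesim_features([("p0", "l0")], net, mask_query_edge=False)
        masked = hetesim_features([("p0", "l0")], net, mask_query_edge=True)
        assert unmasked.scores.max() > 0.0
        assert np.all(masked.scores == 0.0)
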