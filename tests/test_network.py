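"""Signed-network metrics, permutation nulls and duplicate-pair conservation."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ohnolog_forge.errors import InputError
from ohnolog_forge.network import (Edge, SignalNetwork, classify_cie_coe,
                                   find_bridged_pairs, node_metrics,
                                   pair_conservation, permutation_pvalue,
                                   pooled_shared_edge_pct, random_pair_null)

from oracles import brute_betweenness


def net(*triples, nodes=()):
    return SignalNetwork([Edge(*t) for t in triples], nodes=nodes)


class TestSubnetwork:
    def test_all_filter_is_identity(self):
        n = net(("a", "b", "positive"), ("b", "c", "scaffold"))
        assert sorted(n.subnetwork("all").edges) == sorted(n.edges)

    def test_absent_polarity_gives_empty_network(self):
        n = net(("a", "b", "scaffold"), ("b", "c", "scaffold"))
        sub = n.subnetwork("negative")
        assert sub.nodes == [] and sub.n_edges() == 0

    def test_positive_filter_keeps_only_positive(self):
        n = net(("a", "b", "positive"), ("b", "c", "positive"),
                ("a", "c", "negative"))
        sub = n.subnetwork("positive")
        assert sub.n_edges() == 2
        assert all(e.polarity == "positive" for e in sub.edges)

    def test_duplicate_typed_edges_deduplicated(self):
        n = net(("a", "b", "scaffold"), ("b", "a", "scaffold"),
                ("a", "b", "positive"), ("a", "b", "positive"))
        assert n.n_edges() == 2  # canonical scaffold + one positive


class TestNodeMetrics:
    def test_path_middle_node_has_full_betweenness(self):
        n = net(("a", "b", "scaffold"), ("b", "c", "scaffold"))
        m = node_metrics(n)
        assert m.relative_betweenness["b"] == pytest.approx(1.0)
        assert m.relative_betweenness["a"] == 0.0
        assert m.degree == {"a": 1, "b": 2, "c": 1}
        # scaffold-only network: indegree == outdegree == degree
        assert m.indegree == m.degree and m.outdegree == m.degree

    def test_isolated_node_all_zero(self):
        n = net(("a", "b", "scaffold"), nodes=["x"])
        m = node_metrics(n)
        assert (m.degree["x"], m.indegree["x"], m.outdegree["x"],
                m.relative_betweenness["x"]) == (0, 0, 0, 0.0)

    def test_directed_degree_decomposition(self):
        n = net(("a", "b", "positive"), ("c", "b", "negative"),
                ("b", "d", "positive"))
        m = node_metrics(n)
        assert m.indegree["b"] == 2 and m.outdegree["b"] == 1
        assert m.degree["b"] == m.indegree["b"] + m.outdegree["b"]

    def test_typed_parallel_edges_each_count_toward_degree(self):
        n = net(("a", "b", "positive"), ("a", "b", "scaffold"))
        m = node_metrics(n)
        assert m.degree["a"] == 2

    def test_betweenness_matches_path_counting_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(6):
            g = nx.gnp_random_graph(15, 0.25, seed=int(rng.integers(1e6)))
            edges = [(f"n{u}", f"n{v}", "scaffold") for u, v in g.edges]
            n = net(*edges, nodes=[f"n{i}" for i in range(15)])
            m = node_metrics(n)
            expected = brute_betweenness(n.to_networkx(directed=False))
            for node, val in expected.items():
                assert m.relative_betweenness[node] == pytest.approx(val, abs=1e-12)


class TestPermutation:
    def _toy4(self):
        return net(("a", "b", "scaffold"), ("b", "c", "scaffold"),
                   ("c", "d", "scaffold"), ("b", "c", "positive"))

    def test_whole_node_set_gives_p_one(self):
        n = self._toy4()
        res = permutation_pvalue(n, n.nodes, "mean_degree", n_perm=50, seed=1)
        assert res["p_value"] == pytest.approx(1.0)

    def test_exhaustive_p_on_unique_top_pair(self):
        # b and c are the unique two highest-degree nodes: 1 of C(4,2) subsets
        res = permutation_pvalue(self._toy4(), ["b", "c"], "mean_degree",
                                 exhaustive=True)
        assert res["p_value"] == pytest.approx(1 / 6)

    def test_sampled_p_converges_to_exhaustive(self):
        exact = permutation_pvalue(self._toy4(), ["b", "c"], "mean_degree",
                                   exhaustive=True)["p_value"]
        sampled = permutation_pvalue(self._toy4(), ["b", "c"], "mean_degree",
                                     n_perm=4000, seed=3)["p_value"]
        assert abs(sampled - exact) < 0.05

    def test_fixed_seed_reproducible(self):
        n = self._toy4()
        a = permutation_pvalue(n, ["b"], "mean_betweenness", n_perm=200, seed=9)
        b = permutation_pvalue(n, ["b"], "mean_betweenness", n_perm=200, seed=9)
        assert a == b

    def test_empty_node_set_is_input_error(self):
        with pytest.raises(InputError):
            permutation_pvalue(self._toy4(), [], "mean_degree")


class TestPairConservation:
    def test_toy_shared_two_of_three(self):
        n = net(("P1", "C", "positive"), ("P2", "C", "positive"),
                ("P1", "D", "positive"))
        res = pair_conservation(n, [("P1", "P2")])
        rec = res["pairs"][0]
        assert rec.shared_edge_count == 2
        assert rec.total_incident_edges == 3
        assert rec.conserved_fraction == pytest.approx(2 / 3)

    def test_no_common_third_node_zero_shared(self):
        n = net(("P1", "C", "positive"), ("P2", "D", "positive"))
        rec = pair_conservation(n, [("P1", "P2")])["pairs"][0]
        assert rec.shared_edge_count == 0

    def test_polarity_and_direction_must_match(self):
        n = net(("P1", "C", "positive"), ("P2", "C", "negative"),
                ("P1", "D", "positive"), ("D", "P2", "positive"))
        rec = pair_conservation(n, [("P1", "P2")])["pairs"][0]
        assert rec.shared_edge_count == 0

    def test_scaffold_matches_undirected(self):
        n = net(("P1", "C", "scaffold"), ("C", "P2", "scaffold"))
        rec = pair_conservation(n, [("P1", "P2")])["pairs"][0]
        assert rec.shared_edge_count == 2 and rec.conserved_fraction == 1.0

    def test_bridging_edge_excluded_from_both_counts(self):
        n = net(("P1", "P2", "scaffold"), ("P1", "C", "positive"),
                ("P2", "C", "positive"))
        rec = pair_conservation(n, [("P1", "P2")])["pairs"][0]
        assert rec.bridged and rec.total_incident_edges == 2
        assert rec.conserved_fraction == pytest.approx(1.0)

    def test_pooled_percentage_formats_published_counts(self):
        assert pooled_shared_edge_pct(1728, 6741) == pytest.approx(25.63, abs=0.005)
        assert pooled_shared_edge_pct(348, 783) == pytest.approx(44.44, abs=0.005)

    def test_degree_difference_absolute(self):
        n = net(("P1", "C", "positive"), ("P1", "D", "positive"),
                ("P1", "E", "positive"), ("P2", "C", "positive"))
        rec = pair_conservation(n, [("P1", "P2")])["pairs"][0]
        assert rec.degree_difference == 2

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_pair_metrics_symmetric_in_pair_order(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"n{i}" for i in range(8)]
        edges = []
        for _ in range(12):
            u, v = rng.choice(8, size=2, replace=False)
            pol = ["positive", "negative", "scaffold"][int(rng.integers(3))]
            edges.append((names[u], names[v], pol))
        n = net(*edges)
        u, v = names[0], names[1]
        if u not in n or v not in n:
            return
        a = pair_conservation(n, [(u, v)])["pairs"][0]
        b = pair_conservation(n, [(v, u)])["pairs"][0]
        assert a.shared_edge_count == b.shared_edge_count
        assert a.total_incident_edges == b.total_incident_edges
        assert a.degree_difference == b.degree_difference
        assert a.bridged == b.bridged


class TestCieCoe:
    def test_common_regulator_is_cie(self):
        n = net(("R", "P1", "negative"), ("R", "P2", "negative"))
        res = classify_cie_coe(n, ("P1", "P2"))
        assert res["cie"]["negative"] == 1 and res["coe_count"] == 0

    def test_common_target_is_coe(self):
        n = net(("P1", "T", "positive"), ("P2", "T", "positive"))
        res = classify_cie_coe(n, ("P1", "P2"))
        assert res["coe"]["positive"] == 1 and res["cie_count"] == 0

    def test_scaffold_shared_edges_ignored(self):
        n = net(("P1", "C", "scaffold"), ("P2", "C", "scaffold"))
        res = classify_cie_coe(n, ("P1", "P2"))
        assert res["cie_count"] == 0 and res["coe_count"] == 0


class TestBridgedPairs:
    def test_direct_scaffold_edge_is_bridge(self):
        n = net(("P1", "P2", "scaffold"))
        res = find_bridged_pairs(n, [("P1", "P2")])
        assert res["n_bridged"] == 1
        assert res["bridged"][0]["polarities"] == ["scaffold"]

    def test_no_direct_edge_not_bridged(self):
        n = net(("P1", "C", "positive"), ("P2", "C", "positive"))
        assert find_bridged_pairs(n, [("P1", "P2")])["n_bridged"] == 0

    def test_multiple_bridge_types_listed(self):
        n = net(("P1", "P2", "positive"), ("P1", "P2", "scaffold"))
        res = find_bridged_pairs(n, [("P1", "P2")])
        assert res["bridged"][0]["polarities"] == ["positive", "scaffold"]


class TestRandomPairNull:
    def test_complete_graph_every_pair_shares(self):
        edges = [(a, b, "scaffold")
                 for a, b in itertools.combinations("abcde", 2)]
        n = net(*edges)
        res = random_pair_null(n, n_samples=50, seed=1)
        assert res["frac_pairs_any_shared"] == 1.0

    def test_star_graph_matches_enumeration(self):
        leaves = [f"l{i}" for i in range(5)]
        n = net(*[("hub", l, "scaffold") for l in leaves])
        res = random_pair_null(n, exhaustive=True)
        # leaf-leaf pairs share via the hub; hub-leaf pairs share nothing
        n_pairs = math.comb(6, 2)
        expected = math.comb(5, 2) / n_pairs
        assert res["frac_pairs_any_shared"] == pytest.approx(expected)

    def test_edgeless_graph_all_zero(self):
        n = net(nodes=["a", "b", "c"])
        res = random_pair_null(n, n_samples=10, seed=2)
        assert res["expected_shared_fraction"] == 0.0
        assert res["frac_pairs_any_shared"] == 0.0
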