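"""Random-walk distances, modularity, Ward cuts, and the feature catalog."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from protect.genome_io import PPINetwork
from protect.ppi_modules import (
    adjacency,
    detect_modules,
    hierarchical_modules,
    module_feature_catalog,
    modularity,
    rw_distance,
    transition_matrix,
)
from protect.synthetic_fixtures import SimulationConfig, simulate_ppi_network


def net_from_edges(edges, tfs=None):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    tfs = set(tfs if tfs is not None else g.nodes)
    for n in g.nodes:
        g.nodes[n]["is_tf"] = n in tfs
        g.nodes[n]["is_expressed"] = True
    return PPINetwork(graph=g)


def brute_modularity(network, membership, nodes):
    """Independent O(n^2) double-sum evaluation of Q."""
    W = adjacency(network, nodes)
    k = W.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(len(nodes)):
        for j in range(len(nodes)):
            if membership[nodes[i]] == membership[nodes[j]]:
                q += W[i, j] - k[i] * k[j] / two_m
    return q / two_m


class TestTransitionMatrix:
    def test_single_edge_alternates(self):
        net = net_from_edges([("A", "B", 1.0)])
        nodes, T1 = transition_matrix(net, p=1)
        np.testing.assert_allclose(T1, [[0, 1], [1, 0]])
        _, T2 = transition_matrix(net, p=2)
        np.testing.assert_allclose(T2, np.eye(2))

    def test_rows_sum_to_one(self):
        net, _ = simulate_ppi_network(SimulationConfig(seed=3))
        _, T = transition_matrix(net, p=20)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_matrix_power_oracle(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(8, 0.6, seed=1)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(1, 10))
        for n in g.nodes:
            g.nodes[n]["is_tf"] = True
        net = PPINetwork(graph=g)
        nodes, T = transition_matrix(net, p=20)
        W = adjacency(net, nodes)
        T1 = W / W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(T, np.linalg.matrix_power(T1, 20), atol=1e-12)

    def test_isolated_node_dropped(self):
        net = net_from_edges([("A", "B", 1.0)])
        net.graph.add_node("C", is_tf=True, is_expressed=True)
        nodes, T = transition_matrix(net, p=1)
        assert nodes == ["A", "B"] and T.shape == (2, 2)


class TestRwDistance:
    def test_self_distance_zero(self):
        net, _ = simulate_ppi_network(SimulationConfig(seed=3))
        nodes, T = transition_matrix(net, p=20)
        rwd = rw_distance(nodes, T, sorted(net.tf_nodes()))
        assert np.all(np.diag(rwd.R) == 0)
        np.testing.assert_allclose(rwd.R, rwd.R.T)
        assert rwd.R.min() >= 0

    def test_two_node_hand_value(self):
        # p=1 on a single edge: T = [[0,1],[1,0]], G = I, R_12 = 1 + 1 - 0 = 2
        net = net_from_edges([("A", "B", 1.0)])
        nodes, T = transition_matrix(net, p=1)
        rwd = rw_distance(nodes, T, ["A", "B"], p=1)
        assert rwd.R[0, 1] == pytest.approx(2.0)

    def test_identical_profiles_have_zero_distance(self):
        # A and C both connect only to B with equal weight: identical rows
        net = net_from_edges([("A", "B", 2.0), ("C", "B", 2.0)])
        nodes, T = transition_matrix(net, p=2)
        rwd = rw_distance(nodes, T, ["A", "C"])
        assert rwd.R[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_definitional_formula(self):
        net, _ = simulate_ppi_network(SimulationConfig(seed=5))
        nodes, T = transition_matrix(net, p=20)
        rwd = rw_distance(nodes, T, sorted(net.tf_nodes()))
        G = T @ T.T
        idx = {n: i for i, n in enumerate(nodes)}
        for i, a in enumerate(rwd.node_order[:5]):
            for j, b in enumerate(rwd.node_order[:5]):
                expected = G[idx[a], idx[a]] + G[idx[b], idx[b]] - 2 * G[idx[a], idx[b]]
                assert rwd.R[i, j] == pytest.approx(max(expected, 0.0), abs=1e-12)


class TestModularity:
    def test_single_module_zero(self):
        net = net_from_edges([("A", "B", 1.0), ("B", "C", 2.0)])
        assert modularity(net, {"A": 0, "B": 0, "C": 0}) == pytest.approx(0.0, abs=1e-14)

    def test_two_disjoint_edges(self):
        net = net_from_edges([("A", "B", 1.0), ("C", "D", 1.0)])
        q = modularity(net, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert q == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(15, 0.3, seed=seed)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.5, 5))
        for n in g.nodes:
            g.nodes[n]["is_tf"] = True
        net = PPINetwork(graph=g)
        nodes = sorted(g.nodes)
        membership = {n: int(rng.integers(0, 4)) for n in nodes}
        assert modularity(net, membership, nodes) == pytest.approx(
            brute_modularity(net, membership, nodes), abs=1e-12
        )


class TestHierarchicalModules:
    def test_two_cliques_recovered_as_s_modules(self):
        edges = [(a, b, 900.0) for a, b in
                 [("A1", "A2"), ("A1", "A3"), ("A2", "A3"),
                  ("B1", "B2"), ("B1", "B3"), ("B2", "B3")]]
        edges.append(("A1", "B1", 101.0))  # weak bridge
        net = net_from_edges(edges)
        assignment, _ = detect_modules(net, p=4)
        s = assignment.s_module_of
        assert s["A1"] == s["A2"] == s["A3"]
        assert s["B1"] == s["B2"] == s["B3"]
        assert s["A1"] != s["B1"]

    def test_planted_sbm_recovery(self):
        cfg = SimulationConfig(seed=3, n_tfs=48, n_nontf_proteins=0,
                               n_planted_modules=4, within_module_edge_prob=0.9,
                               between_module_edge_prob=0.02)
        net, truth = simulate_ppi_network(cfg)
        assignment, _ = detect_modules(net, p=20)
        tfs = sorted(truth.true_module_of)
        ari = adjusted_rand_score([truth.true_module_of[t] for t in tfs],
                                  [assignment.s_module_of[t] for t in tfs])
        assert ari >= 0.8

    def test_s_cut_maximizes_modularity_curve(self, dataset, modules):
        assignment, _ = modules
        best = max(q for _, q in assignment.modularity_curve)
        s_q = max(q for size, q in assignment.modularity_curve if size == assignment.S_max)
        assert s_q == pytest.approx(best, abs=1e-12)

    def test_s_partition_refines_l_partition(self, modules):
        assignment, _ = modules
        s_to_l = {}
        for tf, s in assignment.s_module_of.items():
            l = assignment.l_module_of[tf]
            assert s_to_l.setdefault(s, l) == l

    def test_module_sizes_respect_maxima(self, modules):
        assignment, _ = modules
        s_sizes = [len(v) for v in assignment.s_members().values()]
        l_sizes = [len(v) for v in assignment.l_members().values()]
        assert max(s_sizes) <= assignment.S_max
        assert max(l_sizes) <= assignment.L_max

    def test_too_few_tfs_raises(self):
        net = net_from_edges([("A", "B", 1.0)], tfs=["A"])
        nodes, T = transition_matrix(net, p=2)
        rwd = rw_distance(nodes, T, ["A"])
        with pytest.raises(ValueError):
            hierarchical_modules(rwd, net)


class TestFeatureCatalog:
    def test_cross_module_ppi_gives_two_directional_features(self):
        edges = [(a, b, 900.0) for a, b in
                 [("A1", "A2"), ("A1", "A3"), ("A2", "A3"),
                  ("B1", "B2"), ("B1", "B3"), ("B2", "B3")]]
        edges.append(("A1", "B1", 110.0))
        net = net_from_edges(edges)
        assignment, catalog = detect_modules(net, p=4)
        assert assignment.s_module_of["A1"] != assignment.s_module_of["B1"]
        s_inter = [f for f in catalog.features if f.kind == "inter" and f.layer == "S"]
        ids = {f.feature_id for f in s_inter}
        ma, mb = assignment.s_module_of["A1"], assignment.s_module_of["B1"]
        assert f"S{ma}>S{mb}" in ids and f"S{mb}>S{ma}" in ids
        fwd = catalog.by_id(f"S{ma}>S{mb}")
        assert fwd.constituents == (("A1", "B1"),)

    def test_intra_module_feature_is_undirectional(self, modules, dataset):
        _, catalog = modules
        intra = [f for f in catalog.features if f.kind == "intra"]
        assert intra, "fixture should produce intra-module features"
        for f in intra:
            pairs = set(f.constituents)
            for a, b in pairs:
                assert (b, a) in pairs  # both orders present

    def test_no_cross_ppi_no_inter_feature(self):
        net = net_from_edges(
            [("A1", "A2", 900.0), ("B1", "B2", 900.0)])
        assignment, catalog = detect_modules(net, p=2)
        inter = [f for f in catalog.features if f.kind == "inter"]
        for f in inter:
            assert f.constituents  # every inter feature backed by a PPI
        # every inter feature must be backed by a bridging PPI in its own layer
        for f in inter:
            ms = (assignment.s_module_of if f.layer == "S" else assignment.l_module_of)
            a, b = f.modules
            members_a = [t for t, m in ms.items() if m == a]
            members_b = [t for t, m in ms.items() if m == b]
            assert any(net.graph.has_edge(x, y) for x in members_a for y in members_b)

    def test_dimension_reduction(self, dataset, modules, feature_data):
        _, catalog = modules
        _, tf_matrix = feature_data
        n_tf_level = tf_matrix.shape[1]
        assert len(catalog.features) < n_tf_level

    def test_directional_pairs_are_mutual(self, modules):
        _, catalog = modules
        for a, b in catalog.directional_pairs():
            fa, fb = catalog.by_id(a), catalog.by_id(b)
            assert fa.modules == fb.modules[::-1]
            assert {(y, x) for x, y in fa.constituents} == set(fb.constituents)
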