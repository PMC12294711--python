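import itertools

import networkx as nx
import numpy as np
import pytest

from effectorank.geneset_io import GeneSet, ValidationError
from effectorank.network import (
    NetworkParams,
    PPINetwork,
    centralities,
    k_step_markov,
    pagerank_with_priors,
    score_candidates_network,
)


def dense_pagerank_oracle(graph, prior, damping, n_iter=20000):
    """Independent dense-matrix power iteration on an explicit walk matrix."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v in graph.edges:
        W[index[v], index[u]] = 1.0
        W[index[u], index[v]] = 1.0
    col = W.sum(axis=0)
    dangling = col == 0
    W = W / np.where(dangling, 1.0, col)
    p = np.array([prior.get(node, 0.0) for node in nodes])
    p = p / p.sum()
    x = p.copy()
    for _ in range(n_iter):
        x = (1 - damping) * p + damping * (W @ x + x[dangling].sum() * p)
    return dict(zip(nodes, x))


def _net(*edges):
    return PPINetwork.from_edges(list(edges))


class TestPageRankWithPriors:
    def test_two_node_symmetry(self):
        net = _net(("a", "b"))
        for d in (0.0, 0.5, 0.85, 0.99):
            scores = pagerank_with_priors(
                net, GeneSet.from_iterable("s", ["a", "b"]), NetworkParams(damping=d)
            )
            assert scores["A"] == pytest.approx(0.5, abs=1e-12)
            assert scores["B"] == pytest.approx(0.5, abs=1e-12)

    def test_zero_damping_returns_prior(self):
        net = _net(("a", "b"), ("b", "c"), ("c", "d"))
        scores = pagerank_with_priors(
            net, GeneSet.from_iterable("s", ["a"]), NetworkParams(damping=0.0)
        )
        assert scores["A"] == pytest.approx(1.0)
        assert scores["B"] == scores["C"] == scores["D"] == 0.0

    def test_path_graph_matches_dense_oracle(self):
        net = _net(("a", "b"), ("b", "c"))
        seeds = GeneSet.from_iterable("s", ["a"])
        scores = pagerank_with_priors(net, seeds, NetworkParams(damping=0.85, tol=1e-14))
        oracle = dense_pagerank_oracle(net.graph, {"A": 1.0}, 0.85)
        for node in scores:
            assert scores[node] == pytest.approx(oracle[node], abs=1e-10)

    def test_random_graphs_match_dense_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 11))
            graph = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            if graph.number_of_edges() == 0:
                graph.add_edge(0, 1)
            net = PPINetwork.from_edges([(f"n{u}", f"n{v}") for u, v in graph.edges])
            nodes = sorted(net.graph.nodes)
            seeds = GeneSet.from_iterable("s", [nodes[0]])
            scores = pagerank_with_priors(net, seeds, NetworkParams(tol=1e-14))
            oracle = dense_pagerank_oracle(net.graph, {nodes[0]: 1.0}, 0.85)
            assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
            for node in scores:
                assert scores[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_matches_networkx_personalized_pagerank(self):
        graph = nx.barabasi_albert_graph(60, 2, seed=5)
        net = PPINetwork.from_edges([(f"n{u}", f"n{v}") for u, v in graph.edges])
        seeds = GeneSet.from_iterable("s", ["n0", "n3", "n7"])
        mine = pagerank_with_priors(net, seeds, NetworkParams(tol=1e-13))
        personalization = {n: 0.0 for n in net.graph.nodes}
        for s in ("N0", "N3", "N7"):
            personalization[s] = 1 / 3
        reference = nx.pagerank(
            net.graph, alpha=0.85, personalization=personalization, tol=1e-13, max_iter=500
        )
        for node in mine:
            assert mine[node] == pytest.approx(reference[node], abs=1e-9)

    def test_relabeling_invariance(self):
        net = _net(("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"))
        seeds = GeneSet.from_iterable("s", ["a"])
        scores = pagerank_with_priors(net, seeds)
        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        relabeled = PPINetwork(nx.relabel_nodes(net.graph, mapping))
        scores2 = pagerank_with_priors(relabeled, GeneSet.from_iterable("s", ["w"]))
        for old, new in mapping.items():
            assert scores[old] == pytest.approx(scores2[new], abs=1e-12)

    def test_missing_seeds_error_names_them(self):
        net = _net(("a", "b"))
        with pytest.raises(ValidationError, match="GHOST"):
            pagerank_with_priors(net, GeneSet.from_iterable("s", ["ghost"]))

    def test_seed_wired_beats_degree_matched_unwired(self):
        # Two degree-3 candidates: one with 2 seed neighbors, one with none.
        rng = np.random.default_rng(23)
        for _ in range(10):
            graph = nx.barabasi_albert_graph(80, 2, seed=int(rng.integers(2**31)))
            net_graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
            seeds = [f"N{i}" for i in rng.choice(80, size=10, replace=False)]
            others = [n for n in net_graph.nodes if n not in seeds]
            wired, unwired = others[0], others[1]
            for node in (wired, unwired):
                net_graph.remove_edges_from(list(net_graph.edges(node)))
            net_graph.add_edges_from([(wired, seeds[0]), (wired, seeds[1]), (wired, others[5])])
            net_graph.add_edges_from([(unwired, others[6]), (unwired, others[7]), (unwired, others[8])])
            scores = pagerank_with_priors(
                PPINetwork(net_graph), GeneSet.from_iterable("s", seeds)
            )
            assert scores[wired] > scores[unwired]


class TestKStepMarkov:
    def test_star_one_step(self):
        net = _net(("hub", "l1"), ("hub", "l2"), ("hub", "l3"), ("hub", "l4"))
        masses = k_step_markov(net, GeneSet.from_iterable("s", ["hub"]), k_steps=1)
        for leaf in ("L1", "L2", "L3", "L4"):
            assert masses[leaf] == pytest.approx(0.25)
        assert masses["HUB"] == 0.0

    def test_star_two_steps_averages_return_mass(self):
        net = _net(("hub", "l1"), ("hub", "l2"), ("hub", "l3"))
        masses = k_step_markov(net, GeneSet.from_iterable("s", ["hub"]), k_steps=2)
        # step 1: all mass on leaves; step 2: all mass back at the hub.
        assert masses["HUB"] == pytest.approx(0.5)
        assert masses["L1"] == pytest.approx((1 / 3) / 2)

    def test_matches_matrix_power_oracle(self):
        rng = np.random.default_rng(31)
        graph = nx.gnp_random_graph(6, 0.5, seed=9)
        if graph.number_of_edges() == 0:
            graph.add_edge(0, 1)
        net = PPINetwork.from_edges([(f"n{u}", f"n{v}") for u, v in graph.edges])
        nodes = sorted(net.graph.nodes)
        seeds = GeneSet.from_iterable("s", nodes[:2])
        k = 3
        masses = k_step_markov(net, seeds, k_steps=k)
        # Dense oracle with explicit matrix powers.
        index = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        W = np.zeros((n, n))
        for u, v in net.graph.edges:
            W[index[v], index[u]] = 1.0
            W[index[u], index[v]] = 1.0
        col = W.sum(axis=0)
        dangling = col == 0
        W = W / np.where(dangling, 1.0, col)
        p = np.zeros(n)
        p[[index[s] for s in nodes[:2]]] = 0.5
        x, acc = p.copy(), np.zeros(n)
        for _ in range(k):
            x = W @ x + x[dangling].sum() * p
            acc += x
        for node in nodes:
            assert masses[node] == pytest.approx(acc[index[node]] / k, abs=1e-12)

    def test_mass_sums_to_one(self):
        net = _net(("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"))
        masses = k_step_markov(net, GeneSet.from_iterable("s", ["a"]), k_steps=5)
        assert sum(masses.values()) == pytest.approx(1.0, abs=1e-12)


class TestCentralities:
    def test_path_graph(self):
        result = centralities(_net(("a", "b"), ("b", "c")))
        assert result["B"] == (2, 1.0)
        assert result["A"] == (1, 0.0)

    def test_complete_graph_betweenness_zero(self):
        nodes = ["a", "b", "c", "d"]
        net = _net(*itertools.combinations(nodes, 2))
        assert all(result[1] == 0.0 for result in centralities(net).values())

    def test_tree_matches_shortest_path_enumeration(self):
        edges = [("r", "a"), ("r", "b"), ("a", "c"), ("a", "d"), ("b", "e"), ("e", "f")]
        net = _net(*edges)
        result = centralities(net)
        # Brute force: count shortest paths through each node over all pairs.
        graph = net.graph
        expected = {node: 0.0 for node in graph.nodes}
        for s, t in itertools.combinations(sorted(graph.nodes), 2):
            paths = list(nx.all_shortest_paths(graph, s, t))
            for path in paths:
                for inner in path[1:-1]:
                    expected[inner] += 1 / len(paths)
        for node in graph.nodes:
            assert result[node][1] == pytest.approx(expected[node], abs=1e-12)


class TestNetworkValidation:
    def test_self_loop_rejected(self):
        with pytest.raises(ValidationError, match="self-loop"):
            PPINetwork.from_edges([("a", "a")])

    def test_bad_weight_rejected(self):
        with pytest.raises(ValidationError, match="weight"):
            PPINetwork.from_edges([("a", "b", 1.5)])

    def test_edgelist_round_trip(self, tmp_path):
        net = _net(("a", "b"), ("b", "c", 0.5))
        path = tmp_path / "edges.tsv"
        net.write_edgelist(path)
        loaded = PPINetwork.from_edgelist_file(path)
        assert set(loaded.graph.edges) == set(net.graph.edges)
        assert loaded.graph["B"]["C"]["weight"] == pytest.approx(0.5)

    def test_candidates_absent_from_network_warn_and_zero(self):
        net = _net(("a", "b"), ("b", "c"))
        with pytest.warns(UserWarning, match="absent"):
            scores = score_candidates_network(
                net, GeneSet.from_iterable("s", ["a"]), ["b", "zzz"]
            )
        by_gene = {s.gene: s for s in scores}
        assert by_gene["ZZZ"].net_score == 0.0
        assert not by_gene["ZZZ"].in_network
        assert by_gene["B"].net_score > 0.0
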