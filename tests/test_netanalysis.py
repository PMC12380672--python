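"""Directed network topology, centralities and hub ranking.

The betweenness and path-metric oracle is a from-scratch BFS that
enumerates every shortest path explicitly — independent of networkx.
"""

import itertools
from collections import deque

import numpy as np
import pytest

from comorbidlink import (
    DirectedGeneNetwork,
    NetworkSpec,
    centralities,
    clustering_coefficient,
    density,
    generate_network,
    hub_genes,
    load_edgelist,
    network_metrics,
    path_metrics,
)
from comorbidlink.netanalysis import write_edgelist


def brute_shortest_paths(nodes, edges):
    """All-pairs shortest paths by BFS, returning every geodesic explicitly."""
    adj = {n: [] for n in nodes}
    for s, t in edges:
        adj[s].append(t)
    paths = {}
    for src in nodes:
        dist = {src: 0}
        geodesics = {src: [[src]]}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    geodesics[v] = [p + [v] for p in geodesics[u]]
                    queue.append(v)
                elif dist[v] == dist[u] + 1:
                    geodesics[v].extend(p + [v] for p in geodesics[u])
        for tgt in nodes:
            if tgt != src and tgt in dist:
                paths[(src, tgt)] = (dist[tgt], geodesics[tgt])
    return paths


def brute_betweenness(nodes, edges):
    paths = brute_shortest_paths(nodes, edges)
    n = len(nodes)
    scores = {v: 0.0 for v in nodes}
    for (s, t), (_, geos) in paths.items():
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in g for g in geos)
            scores[v] += through / len(geos)
    norm = (n - 1) * (n - 2)
    return {v: s / norm for v, s in scores.items()}


def complete_digraph(n):
    names = [f"N{i}" for i in range(n)]
    return DirectedGeneNetwork.from_edges(
        [(a, b) for a, b in itertools.permutations(names, 2)]
    )


class TestDensity:
    def test_nine_node_module_scale(self):
        net = generate_network(NetworkSpec(n_nodes=9, m_edges=29, seed=0))
        assert round(density(net), 2) == 0.40
        assert density(net) == pytest.approx(29 / 72)

    def test_complete_digraph_is_one(self):
        assert density(complete_digraph(5)) == 1.0

    def test_edgeless_is_zero(self):
        net = DirectedGeneNetwork.from_edges([], extra_nodes=[f"N{i}" for i in range(9)])
        assert density(net) == 0.0

    def test_removing_an_edge_never_raises_density(self):
        net = generate_network(NetworkSpec(n_nodes=7, m_edges=20, seed=2))
        smaller = DirectedGeneNetwork.from_edges(
            net.edges[:-1], extra_nodes=net.nodes
        )
        assert density(smaller) < density(net)


class TestPathMetrics:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([("a", "b"), ("b", "c"), ("c", "a")], (1.5, 2)),  # 3-cycle
            ([("a", "b"), ("b", "c")], (4 / 3, 2)),  # directed path
        ],
    )
    def test_hand_enumerated_graphs(self, edges, expected):
        apl, diam = path_metrics(DirectedGeneNetwork.from_edges(edges))
        assert apl == pytest.approx(expected[0])
        assert diam == expected[1]

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_complete_digraph(self, n):
        assert path_metrics(complete_digraph(n)) == (1.0, 1)

    def test_no_reachable_pairs_rejected(self):
        net = DirectedGeneNetwork.from_edges([], extra_nodes=["a", "b"])
        with pytest.raises(ValueError, match="reachable"):
            path_metrics(net)

    def test_matches_bfs_oracle_on_random_digraphs(self):
        rng = np.random.default_rng(0)
        for seed in range(100):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(1, n * (n - 1) + 1))
            net = generate_network(NetworkSpec(n_nodes=n, m_edges=m, seed=seed))
            pairs = [(s, t) for s, t, _ in net.edges]
            oracle = brute_shortest_paths(sorted(net.nodes), pairs)
            if not oracle:
                continue
            lengths = [d for d, _ in oracle.values()]
            apl, diam = path_metrics(net)
            assert apl == pytest.approx(np.mean(lengths))
            assert diam == max(lengths)


class TestClustering:
    def test_triangle(self):
        net = DirectedGeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        assert clustering_coefficient(net) == 1.0

    def test_star_has_no_closed_triads(self):
        net = DirectedGeneNetwork.from_edges(
            [("hub", leaf) for leaf in ("x", "y", "z")]
        )
        assert clustering_coefficient(net) == 0.0

    def test_four_clique_minus_one_edge(self):
        edges = [
            p
            for p in itertools.permutations("abcd", 2)
            if set(p) != {"a", "b"}
        ]
        net = DirectedGeneNetwork.from_edges(edges)
        assert clustering_coefficient(net) == pytest.approx((2 * (2 / 3) + 2 * 1) / 4)


class TestCentralities:
    def test_in_degree_dominant_node(self):
        # 7 of 8 possible in-edges in a 9-node network -> 0.875
        others = [f"N{i}" for i in range(8)]
        edges = [(o, "TARGET") for o in others[:7]]
        net = DirectedGeneNetwork.from_edges(edges, extra_nodes=others + ["TARGET"])
        prof = centralities(net, damping=0.0)
        assert prof.in_degree["TARGET"] == pytest.approx(0.875)
        assert round(prof.in_degree["TARGET"], 2) == 0.88

    def test_complete_digraph_betweenness_zero(self):
        prof = centralities(complete_digraph(5))
        assert all(v == 0.0 for v in prof.betweenness.values())

    def test_directed_star_out_degrees(self):
        net = DirectedGeneNetwork.from_edges(
            [("c", leaf) for leaf in ("x", "y", "z")]
        )
        prof = centralities(net)
        assert prof.out_degree["c"] == 1.0
        assert prof.out_degree["x"] == 0.0

    def test_betweenness_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for seed in range(100):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(n, n * (n - 1) + 1))
            net = generate_network(NetworkSpec(n_nodes=n, m_edges=m, seed=1000 + seed))
            oracle = brute_betweenness(sorted(net.nodes), [(s, t) for s, t, _ in net.edges])
            prof = centralities(net)
            for node in net.nodes:
                assert prof.betweenness[node] == pytest.approx(oracle[node], abs=1e-12)

    def test_eigenvector_max_norm_one(self):
        net = generate_network(NetworkSpec(n_nodes=9, m_edges=29, seed=6))
        prof = centralities(net)
        assert max(prof.eigenvector.values()) == pytest.approx(1.0)
        assert min(prof.eigenvector.values()) >= 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        net = generate_network(NetworkSpec(n_nodes=8, m_edges=25, seed=3))
        mapping = dict(
            zip(sorted(net.nodes), rng.permutation([f"X{i}" for i in range(8)]))
        )
        relabeled = DirectedGeneNetwork.from_edges(
            [(mapping[s], mapping[t], g) for s, t, g in net.edges]
        )
        p1, p2 = centralities(net), centralities(relabeled)
        for node in net.nodes:
            assert p1.in_degree[node] == pytest.approx(p2.in_degree[mapping[node]])
            assert p1.betweenness[node] == pytest.approx(p2.betweenness[mapping[node]])
            assert p1.eigenvector[node] == pytest.approx(
                p2.eigenvector[mapping[node]], abs=1e-6
            )
        assert density(net) == density(relabeled)
        assert clustering_coefficient(net) == pytest.approx(
            clustering_coefficient(relabeled)
        )


class TestHubGenes:
    def test_dominant_node_ranks_first(self):
        others = [f"N{i}" for i in range(4)]
        edges = [("HUB", o) for o in others] + [(o, "HUB") for o in others]
        net = DirectedGeneNetwork.from_edges(edges)
        assert hub_genes(centralities(net), k=1) == ["HUB"]

    def test_symmetric_tie_broken_lexicographically(self):
        net = DirectedGeneNetwork.from_edges([("a", "b"), ("b", "a")])
        assert hub_genes(centralities(net), k=2) == ["a", "b"]

    def test_engineered_four_dominators(self):
        """Four nodes wired to dominate every centrality come out on top."""
        core = ["C1", "C2", "C3", "C4"]
        periphery = [f"P{i}" for i in range(5)]
        edges = [(a, b) for a, b in itertools.permutations(core, 2)]
        edges += [(c, p) for c, p in zip(core, periphery)]
        edges += [(periphery[4], core[0])]
        net = DirectedGeneNetwork.from_edges(edges)
        assert sorted(hub_genes(centralities(net), k=4)) == core


class TestEdgelistIO:
    def test_three_rows(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("source\ttarget\tsign\na\tb\t+\nb\tc\t-\nc\ta\t+\n")
        net = load_edgelist(p)
        assert net.n_edges == 3

    def test_duplicate_collapsed_with_warning(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        p.write_text("source\ttarget\na\tb\na\tb\nb\tc\n")
        import logging

        with caplog.at_level(logging.WARNING, logger="comorbidlink.netanalysis"):
            net = load_edgelist(p)
        assert net.n_edges == 2
        assert any("duplicate" in m for m in caplog.messages)

    def test_self_loop_rejected_and_logged(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        p.write_text("source\ttarget\na\ta\nb\tc\n")
        import logging

        with caplog.at_level(logging.WARNING, logger="comorbidlink.netanalysis"):
            net = load_edgelist(p)
        assert net.n_edges == 1

    def test_generator_roundtrip(self, tmp_path):
        net = generate_network(NetworkSpec(n_nodes=9, m_edges=29, seed=14))
        out = tmp_path / "net.tsv"
        write_edgelist(net, out)
        assert load_edgelist(out) == net


def test_network_metrics_report():
    net = generate_network(NetworkSpec(n_nodes=9, m_edges=29, seed=0))
    m = network_metrics(net)
    assert m.density == pytest.approx(29 / 72)
    assert m.connected_component_count == 1
    assert 0.0 <= m.clustering_coefficient <= 1.0
    assert m.diameter >= 1
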