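import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radgrn import measures
from radgrn.measures import (
    centrality_features,
    degree_distribution,
    density,
    diameter_and_paths,
    girth,
    jaccard,
    spectral_gaps,
    subgraph_centrality,
    summarize,
)
from conftest import random_graph


def sc_series_oracle(graph: nx.Graph, terms: int = 40) -> dict:
    """Truncated factorial series sum_{r=0..terms} (A^r)_{ii} / r!."""
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    acc = np.eye(len(nodes))
    P = np.eye(len(nodes))
    fact = 1.0
    for r in range(1, terms + 1):
        P = P @ A
        fact *= r
        acc += P / fact
    return dict(zip(nodes, np.diag(acc)))


small_graphs = st.builds(
    lambda n, bits: nx.from_numpy_array(
        np.triu(
            np.array(bits[: n * n]).reshape(n, n) if n else np.zeros((0, 0)),
            k=1,
        )
        + np.triu(
            np.array(bits[: n * n]).reshape(n, n) if n else np.zeros((0, 0)),
            k=1,
        ).T
    ),
    st.integers(min_value=1, max_value=8),
    st.lists(st.integers(0, 1), min_size=64, max_size=64),
)


class TestDegreeDistribution:
    def test_triangle(self):
        table, hist = degree_distribution(nx.cycle_graph(3))
        assert (table["degree_total"] == 2).all()
        assert hist == {2: 1.0}

    def test_star_12_leaves(self):
        table, hist = degree_distribution(nx.star_graph(12))
        assert table.loc[0, "degree_total"] == 12
        assert (table.loc[1:, "degree_total"] == 1).all()
        assert sum(hist.values()) == pytest.approx(1.0)

    def test_handshake_random_graph(self):
        g = random_graph(30, 0.2, seed=1)
        table, _ = degree_distribution(g)
        assert table["degree_total"].sum() == 2 * g.number_of_edges()

    def test_directed_in_out(self):
        g = nx.DiGraph([(0, 1), (0, 2), (1, 2)])
        table, _ = degree_distribution(g)
        assert table.loc[2, "degree_in"] == 2
        assert table.loc[0, "degree_out"] == 2
        assert table.loc[0, "degree_in"] == 0


class TestSubgraphCentrality:
    def test_isolated_node_is_one(self):
        g = nx.Graph()
        g.add_node("x")
        assert subgraph_centrality(g)["x"] == pytest.approx(1.0)

    def test_single_edge_endpoint_cosh1(self):
        g = nx.Graph([("a", "b")])
        assert subgraph_centrality(g)["a"] == pytest.approx(
            math.cosh(1.0), abs=5e-5
        )

    @pytest.mark.parametrize("n", [1, 2, 4, 6, 7, 9, 12, 20])
    def test_star_closed_forms(self, n):
        # hub = cosh(sqrt(n)); leaf = 1 + (cosh(sqrt(n)) - 1)/n
        sc = subgraph_centrality(nx.star_graph(n))
        hub_expected = math.cosh(math.sqrt(n))
        assert sc[0] == pytest.approx(hub_expected, rel=1e-10)
        assert sc[1] == pytest.approx(1 + (hub_expected - 1) / n, rel=1e-10)

    def test_weights_ignored(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.31)
        assert subgraph_centrality(g)["a"] == pytest.approx(math.cosh(1.0))

    def test_minimum_value_one(self):
        g = random_graph(15, 0.2, seed=3)
        assert (subgraph_centrality(g) >= 1.0 - 1e-12).all()

    @settings(max_examples=60, deadline=None)
    @given(small_graphs)
    def test_eigendecomposition_equals_series(self, g):
        # [DERIVED] truncated power-series oracle on all graphs <= 8 nodes
        sc = subgraph_centrality(g)
        oracle = sc_series_oracle(g)
        for node, val in oracle.items():
            assert sc[node] == pytest.approx(val, abs=1e-8)

    def test_matches_networkx(self):
        g = random_graph(12, 0.3, seed=9)
        g.remove_nodes_from(list(nx.isolates(g)))
        ours = subgraph_centrality(g)
        theirs = nx.subgraph_centrality(g)
        for node in g.nodes:
            assert ours[node] == pytest.approx(theirs[node], rel=1e-9)


class TestSpectralGaps:
    @pytest.mark.parametrize("n", [3, 4, 5, 8])
    def test_complete_graph_closed_form(self, n):
        # [DERIVED] K_n normalized adjacency eigenvalues: 1, -1/(n-1)
        _, norm_gap = spectral_gaps(nx.complete_graph(n))
        assert norm_gap == pytest.approx(1 - 1 / (n - 1), abs=1e-10)

    def test_disconnected_gap_zero(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        _, norm_gap = spectral_gaps(g)
        assert norm_gap == pytest.approx(0.0, abs=1e-10)

    def test_bipartite_gap_zero(self):
        _, norm_gap = spectral_gaps(nx.complete_bipartite_graph(3, 4))
        assert norm_gap == pytest.approx(0.0, abs=1e-10)

    def test_single_edge_adjacency_gap_zero(self):
        # [DERIVED] 2x2 eigen oracle: eigenvalues +-1
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        adj_gap, norm_gap = spectral_gaps(g)
        assert adj_gap == pytest.approx(0.0, abs=1e-12)
        assert norm_gap == pytest.approx(0.0, abs=1e-12)

    def test_all_isolated_normalized_undefined(self, caplog):
        g = nx.empty_graph(3)
        with caplog.at_level("WARNING"):
            adj_gap, norm_gap = spectral_gaps(g)
        assert norm_gap is None

    def test_normalized_gap_in_unit_interval(self):
        for seed in range(10):
            g = random_graph(12, 0.25, seed=seed)
            _, norm_gap = spectral_gaps(g)
            if norm_gap is not None:
                assert 0.0 <= norm_gap <= 1.0

    def test_weighted_vs_binary_adjacency(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=2.0)
        g.add_edge("b", "c", weight=2.0)
        weighted, _ = spectral_gaps(g, weighted=True)
        binary, _ = spectral_gaps(g, weighted=False)
        assert weighted == pytest.approx(2 * binary)


class TestGirth:
    def test_directed_triangle(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        assert girth(g) == 3

    def test_dag_infinite(self):
        g = nx.DiGraph([(0, 1), (0, 2), (1, 3), (2, 3)])
        assert girth(g) == math.inf

    def test_undirected_edge_gives_two(self):
        # documented degeneracy of the trace definition on undirected graphs
        assert girth(nx.path_graph(4)) == 2

    def test_matches_shortest_cycle_enumeration(self):
        # [DERIVED] exhaustive simple-cycle search oracle on digraphs <= 7
        for seed in range(25):
            g = random_graph(7, 0.25, seed=seed, directed=True)
            cycles = [len(c) for c in nx.simple_cycles(g)]
            expected = min(cycles) if cycles else math.inf
            assert girth(g) == expected


class TestDiameterPathsDensity:
    def test_single_edge(self):
        d, avg, ncomp = diameter_and_paths(nx.path_graph(2))
        assert (d, avg, ncomp) == (1, 1.0, 1)

    def test_two_disjoint_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        d, avg, ncomp = diameter_and_paths(g)
        assert d == 1 and ncomp == 2

    def test_path_graph_bfs_oracle(self):
        # [DERIVED] all-pairs BFS oracle on P6
        g = nx.path_graph(6)
        d, avg, ncomp = diameter_and_paths(g)
        dists = [
            abs(i - j) for i in range(6) for j in range(6) if i != j
        ]
        assert d == 5
        assert avg == pytest.approx(sum(dists) / len(dists))
        assert ncomp == 1

    def test_random_graph_against_bfs(self):
        for seed in range(5):
            g = random_graph(25, 0.12, seed=seed)
            d, avg, ncomp = diameter_and_paths(g)
            assert ncomp == nx.number_connected_components(g)
            expected_d = max(
                (
                    max(nx.eccentricity(g.subgraph(c)).values())
                    for c in nx.connected_components(g)
                    if len(c) > 1
                ),
                default=0,
            )
            assert d == expected_d or (d == math.inf and expected_d == 0)

    def test_density_complete(self):
        assert density(nx.complete_graph(6)) == pytest.approx(1.0)

    def test_density_edgeless(self):
        assert density(nx.empty_graph(5)) == 0.0

    def test_density_derived(self):
        # [DERIVED] 3 edges over C(4,2)=6 possible
        g = nx.Graph([(0, 1), (1, 2), (2, 3)])
        assert density(g) == pytest.approx(0.5)

    def test_density_matches_networkx(self):
        for seed in range(5):
            g = random_graph(10, 0.3, seed=seed)
            assert density(g) == pytest.approx(nx.density(g))

    def test_density_single_node_rejected(self):
        with pytest.raises(ValueError):
            density(nx.empty_graph(1))

    def test_permutation_invariance(self):
        g = random_graph(10, 0.3, seed=6)
        relabeled = nx.relabel_nodes(g, {i: f"n{9 - i}" for i in range(10)})
        assert density(g) == pytest.approx(density(relabeled))
        assert summarize(g).spectral_gap_adjacency == pytest.approx(
            summarize(relabeled).spectral_gap_adjacency
        )


class TestJaccard:
    def test_identical_neighborhoods(self):
        g = nx.star_graph(4)
        h = nx.star_graph(4)
        pair = jaccard(g, 0, h, 0)
        assert pair.index == 1.0

    def test_disjoint(self):
        g = nx.Graph([("u", "a"), ("v", "b")])
        assert jaccard(g, "u", g, "v").index == 0.0

    def test_enumerated_half(self):
        # [DERIVED] N(u)={a,b,c}, N(v)={b,c,d} -> 2/4
        g = nx.Graph(
            [("u", "a"), ("u", "b"), ("u", "c"), ("v", "b"), ("v", "c"),
             ("v", "d")]
        )
        assert jaccard(g, "u", g, "v").index == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        g = random_graph(12, 0.3, seed=2)
        for u in range(6):
            for v in range(6, 12):
                a = jaccard(g, u, g, v).index
                b = jaccard(g, v, g, u).index
                assert a == b
                assert 0.0 <= a <= 1.0

    def test_both_empty_warns_zero(self):
        g = nx.empty_graph(2)
        with pytest.warns(UserWarning):
            assert jaccard(g, 0, g, 1).index == 0.0

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError):
            jaccard(nx.path_graph(2), 99)


class TestCentralityFeatures:
    def test_star_hub_dominates(self):
        table = centrality_features(nx.star_graph(8))
        hub = table.loc[0]
        leaves = table.drop(index=0)
        for col in ("closeness", "pagerank", "eigenvector",
                    "subgraph_centrality"):
            assert (hub[col] > leaves[col]).all() or hub[col] > leaves[col].max()

    def test_ring_all_equal(self):
        table = centrality_features(nx.cycle_graph(7))
        for col in table.columns:
            assert table[col].nunique() == 1 or np.allclose(
                table[col], table[col].iloc[0]
            )

    def test_pagerank_sums_to_one(self):
        g = random_graph(50, 0.08, seed=4)
        table = centrality_features(g)
        assert table["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvector_l2_normalized_on_giant(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.path_graph(3))
        table = centrality_features(g)
        assert np.linalg.norm(table["eigenvector"]) == pytest.approx(1.0)
        # nodes outside the largest component get zeros
        assert (table.loc[5:, "eigenvector"] == 0).all()

    def test_edgeless_eigenvector_warns_zero(self):
        with pytest.warns(UserWarning):
            table = centrality_features(nx.empty_graph(3))
        assert (table["eigenvector"] == 0).all()


class TestSummarize:
    def test_component_sizes_sum(self):
        g = random_graph(20, 0.1, seed=5)
        summ = summarize(g)
        sizes = [len(c) for c in nx.connected_components(g)]
        assert summ.n_components == len(sizes)
        assert sum(sizes) == summ.n_nodes == 20

    def test_to_dict_json_safe(self):
        import json

        g = nx.DiGraph([(0, 1)])  # acyclic: girth is infinite
        payload = summarize(g).to_dict()
        assert payload["girth"] is None
        json.dumps(payload)

    def test_eigenvalues_sorted_descending(self):
        summ = summarize(random_graph(10, 0.4, seed=7))
        ev = summ.eigenvalues
        assert ev == sorted(ev, reverse=True)
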