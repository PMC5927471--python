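"""Centralities, centralization, Bray-Curtis graph dissimilarity,
edge perturbation -- all checked against dense brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

import oracles
from conftest import make_sample_graphs
from phagenet import (bray_curtis_centrality, centrality, centralization,
                      dissimilarity_matrix, graph_dissimilarity,
                      noise_sweep, perturb_edges)


def random_graph(rng, n_max=30, weighted=False):
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.15, 0.8))
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    if G.number_of_edges() == 0:
        G.add_edge(0, 1)
    if weighted:
        for _, _, d in G.edges(data=True):
            d["weight"] = float(rng.uniform(0.05, 2.0))
    return G


class TestCentralityFixtures:
    def test_triangle_degree(self):
        G = nx.cycle_graph(3)
        assert centrality(G, "degree") == {0: 2.0, 1: 2.0, 2: 2.0}

    def test_path_closeness_printed_formula(self):
        G = nx.path_graph(["A", "B", "C"])
        c = centrality(G, "closeness")
        assert c["B"] == pytest.approx(0.5)
        assert c["A"] == pytest.approx(1 / 3)
        assert c["C"] == pytest.approx(1 / 3)

    def test_normalized_closeness_variant(self):
        G = nx.path_graph(["A", "B", "C"])
        c = centrality(G, "closeness", normalized=True)
        assert c["B"] == pytest.approx(1.0)
        assert c["A"] == pytest.approx(2 / 3)

    def test_star_eigenvector_against_eigendecomposition(self):
        G = nx.star_graph(3)  # center 0, three leaves
        c = centrality(G, "eigenvector")
        assert c[0] == pytest.approx(1.0)
        for leaf in (1, 2, 3):
            assert c[leaf] == pytest.approx(1 / math.sqrt(3), abs=1e-8)
        oracle = oracles.eigenvector_centrality_oracle(G)
        for v in G.nodes:
            assert c[v] == pytest.approx(oracle[v], abs=1e-8)

    def test_weighted_degree_sums_incident_weights(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=0.25)
        G.add_edge("a", "c", weight=0.5)
        c = centrality(G, "degree", weighted=True)
        assert c["a"] == pytest.approx(0.75)

    def test_disconnected_eigenvector_zeroes_minor_component(self):
        G = nx.Graph([("a", "b"), ("a", "c"), ("x", "y")])
        c = centrality(G, "eigenvector")
        assert c["x"] == 0.0 and c["y"] == 0.0
        assert c["a"] == 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            centrality(nx.path_graph(3), "betweenness")


class TestCentralityOracleEquivalence:
    """Dense-matrix oracles (Floyd-Warshall distances, full eigh) agree
    with the implementation on random graphs to 1e-8."""

    @pytest.mark.parametrize("kind,weighted", [
        ("degree", False), ("degree", True),
        ("closeness", False), ("closeness", True),
        ("eigenvector", False), ("eigenvector", True),
    ])
    def test_random_graphs(self, kind, weighted):
        rng = np.random.default_rng(hash((kind, weighted)) % 2**31)
        oracle = {"degree": oracles.degree_centrality_oracle,
                  "closeness": oracles.closeness_centrality_oracle,
                  "eigenvector": oracles.eigenvector_centrality_oracle}[kind]
        for _ in range(15):
            G = random_graph(rng, weighted=weighted)
            got = centrality(G, kind, weighted=weighted)
            want = oracle(G, weighted)
            for v in G.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-8)


class TestCentralization:
    def test_star_degree_is_one(self):
        s = centralization(nx.star_graph(5), "degree")
        assert s.value == pytest.approx(1.0)

    def test_complete_graph_is_zero(self):
        s = centralization(nx.complete_graph(6), "degree")
        assert s.value == pytest.approx(0.0)

    def test_value_in_unit_interval_and_matches_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            G = random_graph(rng, n_max=20)
            connected = nx.is_connected(G)
            for kind in ("degree", "closeness", "eigenvector"):
                if kind == "closeness" and not connected:
                    continue
                s = centralization(G, kind)
                if connected:
                    # the star normalizer bounds connected graphs; on
                    # disconnected ones the zeroed minor components can
                    # push the eigenvector numerator past the star's
                    assert -1e-9 <= s.value <= 1 + 1e-9
                assert s.value == pytest.approx(
                    oracles.centralization_oracle(G, kind), abs=1e-8)

    def test_single_node_rejected(self):
        G = nx.Graph()
        G.add_node("a")
        with pytest.raises(ValueError):
            centralization(G, "degree")


class TestGraphDissimilarity:
    def test_self_dissimilarity_zero(self):
        _, graphs, _ = make_sample_graphs(3)
        G = next(iter(graphs.values()))
        assert graph_dissimilarity(G, G).value == pytest.approx(0.0)

    def test_disjoint_node_sets_give_one(self):
        b = bray_curtis_centrality({"a": 1.0, "b": 0.5},
                                   {"x": 0.7, "y": 0.2})
        assert b.value == pytest.approx(1.0)
        assert b.shared_lesser_sum == 0.0

    def test_worked_example(self):
        # C_ij = 1.0, C_i = 1.5, C_j = 1.25 -> B = 1 - 2/2.75
        b = bray_curtis_centrality({"a": 1.0, "b": 0.5},
                                   {"a": 0.5, "b": 0.5, "c": 0.25})
        assert b.shared_lesser_sum == pytest.approx(1.0)
        assert b.total_i == pytest.approx(1.5)
        assert b.total_j == pytest.approx(1.25)
        assert b.value == pytest.approx(1 - 2 / 2.75)

    def test_vertex_count_totals_variant(self):
        b = bray_curtis_centrality({"a": 1.0, "b": 0.5},
                                   {"a": 0.5, "b": 0.5, "c": 0.25},
                                   totals="vertices")
        assert b.value == pytest.approx(1 - 2 * 1.0 / 5)

    def test_symmetry_and_range_on_random_signatures(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 12, size=2)
            shared = int(rng.integers(0, min(n1, n2) + 1))
            c1 = {f"s{i}": float(rng.uniform(0.01, 1)) for i in range(shared)}
            c1.update({f"a{i}": float(rng.uniform(0.01, 1))
                       for i in range(n1 - shared)})
            c2 = {f"s{i}": float(rng.uniform(0.01, 1)) for i in range(shared)}
            c2.update({f"b{i}": float(rng.uniform(0.01, 1))
                       for i in range(n2 - shared)})
            b12 = bray_curtis_centrality(c1, c2).value
            b21 = bray_curtis_centrality(c2, c1).value
            assert b12 == pytest.approx(b21)
            assert -1e-12 <= b12 <= 1 + 1e-12

    def test_empty_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_centrality({}, {})


class TestDissimilarityMatrix:
    def test_matrix_contract(self):
        _, graphs, _ = make_sample_graphs(4)
        D = dissimilarity_matrix(graphs)
        assert list(D.index) == list(D.columns) == list(graphs)
        np.testing.assert_allclose(D.to_numpy(), D.to_numpy().T)
        np.testing.assert_allclose(np.diag(D.to_numpy()), 0.0)
        # entries equal the pairwise operation
        ids = list(graphs)
        b = graph_dissimilarity(graphs[ids[0]], graphs[ids[1]]).value
        assert D.iloc[0, 1] == pytest.approx(b)

    def test_sample_order_permutes_consistently(self):
        _, graphs, _ = make_sample_graphs(5)
        ids = list(graphs)
        D1 = dissimilarity_matrix(graphs)
        D2 = dissimilarity_matrix({s: graphs[s] for s in reversed(ids)})
        for a in ids:
            for b in ids:
                assert D1.loc[a, b] == pytest.approx(D2.loc[a, b])


class TestPerturbEdges:
    def test_remove_keeps_requested_fraction(self):
        _, graphs, _ = make_sample_graphs(6)
        G = next(iter(graphs.values()))
        m = G.number_of_edges()
        H = perturb_edges(G, "remove", keep_fraction=0.6, seed=0)
        assert H.number_of_edges() == math.floor(0.6 * m)
        assert set(H.nodes) == set(G.nodes)
        assert set(H.edges) <= set(G.edges) | \
            {(v, u) for u, v in G.edges}

    def test_keep_fraction_one_is_identity(self):
        _, graphs, _ = make_sample_graphs(6)
        G = next(iter(graphs.values()))
        H = perturb_edges(G, "remove", keep_fraction=1.0, seed=0)
        assert nx.utils.graphs_equal(G, H)

    def test_complete_mode_connects_all_cross_role_pairs(self):
        _, graphs, _ = make_sample_graphs(6)
        G = next(iter(graphs.values()))
        H = perturb_edges(G, "complete")
        p = sum(1 for _, d in H.nodes(data=True) if d["role"] == "phage")
        b = H.number_of_nodes() - p
        assert H.number_of_edges() == p * b
        assert all("weight" in d for _, _, d in H.edges(data=True))

    def test_invalid_mode_and_fraction(self):
        G = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            perturb_edges(G, "rewire")
        with pytest.raises(ValueError):
            perturb_edges(G, "remove", keep_fraction=0.0)

    def test_seed_determinism(self):
        _, graphs, _ = make_sample_graphs(6)
        G = next(iter(graphs.values()))
        H1 = perturb_edges(G, "remove", 0.5, seed=9)
        H2 = perturb_edges(G, "remove", 0.5, seed=9)
        assert set(H1.edges) == set(H2.edges)


class TestNoiseSweep:
    def test_output_contract(self):
        _, graphs, _ = make_sample_graphs(7)

        def edge_count_stat(gs):
            return min(1.0, max(1e-6, np.mean(
                [g.number_of_edges() for g in gs.values()]) / 1e6))

        table = noise_sweep(graphs, edge_count_stat,
                            fractions=[1.0, 0.8, 0.6, 0.4, 0.2],
                            n_iter=5, seed=0)
        assert len(table) == 5
        assert list(table.columns) == ["keep_fraction", "mean_p", "se_p",
                                       "n_iter"]
        assert (table["n_iter"] == 5).all()
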