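"""Graph metrics, null models and AUC integration."""

import numpy as np
import networkx as nx
import pytest

from braintopo.connectome import sparsity_grid
from braintopo.topology import (
    auc_over_grid,
    characteristic_path_length_harmonic,
    clustering_coefficient,
    efficiencies,
    nodal_degree_betweenness,
    null_cp_lp_means,
    random_null_ensemble,
    small_world_indices,
    _cp_lp,
)
from conftest import adjacency_from_edges


class TestClustering:
    def test_complete_graph_fully_clustered(self, complete_graph):
        c_p, nodal = clustering_coefficient(complete_graph(4))
        assert c_p == 1.0
        np.testing.assert_array_equal(nodal, 1.0)

    def test_path_graph_triangle_free(self, path_graph):
        c_p, nodal = clustering_coefficient(path_graph(4))
        assert c_p == 0.0

    def test_k4_minus_edge_nodal_values(self):
        # edges: complete on {0,1,2,3} minus (2,3)
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])
        _, nodal = clustering_coefficient(adj)
        # exhaustive triangle count: node 0 has neighbour pairs (1,2),(1,3),(2,3)
        # of which 2 are edges; node 2 has pair (0,1), an edge.
        np.testing.assert_allclose(nodal, [2 / 3, 2 / 3, 1.0, 1.0])

    def test_matches_networkx_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnp_random_graph(15, 0.3, seed=seed)
            adj = adjacency_from_edges(15, list(g.edges))
            c_p, nodal = clustering_coefficient(adj)
            nx_clust = nx.clustering(g)
            np.testing.assert_allclose(nodal, [nx_clust[i] for i in range(15)],
                                       atol=1e-12)


class TestPathLengthAndEfficiency:
    def test_complete_graph_unit_path_length(self, complete_graph):
        assert characteristic_path_length_harmonic(complete_graph(6)) == 1.0
        e_glob, e_loc, nodal = efficiencies(complete_graph(6))
        assert e_glob == 1.0 and e_loc == 1.0

    def test_path3_hand_enumeration(self, path_graph):
        # distances 1, 1, 2 -> harmonic mean Lp = 3 / (1 + 1 + 0.5)
        assert characteristic_path_length_harmonic(path_graph(3)) == pytest.approx(1.2)
        e_glob, _, _ = efficiencies(path_graph(3))
        assert e_glob == pytest.approx((1 + 1 + 0.5) / 3)

    def test_disconnected_pairs_still_finite(self):
        adj = adjacency_from_edges(4, [(0, 1), (2, 3)])
        # finite pairs: (0,1) and (2,3); Lp = 6 / 2
        assert characteristic_path_length_harmonic(adj) == pytest.approx(3.0)

    def test_edgeless_graph_infinite_lp_zero_eglob(self):
        adj = adjacency_from_edges(4, [])
        e_glob, e_loc, _ = efficiencies(adj)
        assert e_glob == 0.0
        with pytest.warns(UserWarning, match="no finite-distance"):
            assert characteristic_path_length_harmonic(adj) == np.inf

    def test_harmonic_identity_lp_times_eglob(self):
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.15, seed=seed)
            if g.number_of_edges() == 0:
                continue
            adj = adjacency_from_edges(20, list(g.edges))
            e_glob, _, _ = efficiencies(adj)
            l_p = characteristic_path_length_harmonic(adj)
            assert l_p * e_glob == pytest.approx(1.0, abs=1e-12)

    def test_adding_edge_never_decreases_efficiency_or_degree(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.2, seed=5)
        adj = adjacency_from_edges(12, list(g.edges))
        e_glob, _, nodal = efficiencies(adj)
        deg, _ = nodal_degree_betweenness(adj)
        missing = [(i, j) for i in range(12) for j in range(i + 1, 12)
                   if not adj.entries[i, j]]
        i, j = missing[rng.integers(len(missing))]
        bigger = adjacency_from_edges(12, list(g.edges) + [(i, j)])
        e_glob2, _, nodal2 = efficiencies(bigger)
        deg2, _ = nodal_degree_betweenness(bigger)
        assert e_glob2 >= e_glob
        assert np.all(nodal2 >= nodal - 1e-12)
        assert np.all(deg2 >= deg)


class TestBetweenness:
    def test_star_centre_carries_all_paths(self):
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        _, bc = nodal_degree_betweenness(adj)
        np.testing.assert_allclose(bc, [3.0, 0.0, 0.0, 0.0])

    def test_complete_graph_zero_betweenness(self, complete_graph):
        _, bc = nodal_degree_betweenness(complete_graph(5))
        np.testing.assert_array_equal(bc, 0.0)

    def test_handshake_identity(self):
        g = nx.gnp_random_graph(14, 0.25, seed=2)
        adj = adjacency_from_edges(14, list(g.edges))
        deg, _ = nodal_degree_betweenness(adj)
        assert deg.sum() == 2 * adj.n_edges


class TestNullModels:
    def test_degree_sequence_preserved(self):
        g = nx.watts_strogatz_graph(30, 6, 0.2, seed=1)
        adj = adjacency_from_edges(30, list(g.edges))
        for null in random_null_ensemble(adj, 5, seed=3):
            np.testing.assert_array_equal(
                null.entries.sum(axis=1), adj.entries.sum(axis=1)
            )

    def test_fixed_seed_reproducible(self):
        g = nx.watts_strogatz_graph(20, 4, 0.1, seed=2)
        adj = adjacency_from_edges(20, list(g.edges))
        e1 = random_null_ensemble(adj, 4, seed=9)
        e2 = random_null_ensemble(adj, 4, seed=9)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.entries, b.entries)

    def test_rewiring_destroys_lattice_clustering(self):
        g = nx.watts_strogatz_graph(40, 6, 0.0, seed=0)  # pure ring lattice
        adj = adjacency_from_edges(40, list(g.edges))
        c_input, _ = clustering_coefficient(adj)
        nulls = random_null_ensemble(adj, 20, seed=5)
        c_null = np.mean([clustering_coefficient(n)[0] for n in nulls])
        assert c_null < 0.5 * c_input

    def test_star_admits_no_swap_returns_copies(self):
        adj = adjacency_from_edges(5, [(0, i) for i in range(1, 5)])
        with pytest.warns(UserWarning, match="no double-edge swap"):
            nulls = random_null_ensemble(adj, 3, seed=1)
        for n in nulls:
            np.testing.assert_array_equal(n.entries, adj.entries)

    def test_fused_means_match_ensemble_path(self):
        g = nx.watts_strogatz_graph(30, 6, 0.2, seed=4)
        adj = adjacency_from_edges(30, list(g.edges))
        ens = random_null_ensemble(adj, 6, seed=21)
        stats = np.array([_cp_lp(n.entries) for n in ens])
        cp_mean, lp_mean = null_cp_lp_means(adj, 6, seed=21)
        assert cp_mean == pytest.approx(stats[:, 0].mean(), abs=1e-12)
        assert lp_mean == pytest.approx(stats[:, 1].mean(), abs=1e-12)


class TestSmallWorld:
    def test_identity_null_gives_unit_indices(self):
        g = nx.watts_strogatz_graph(20, 4, 0.1, seed=3)
        adj = adjacency_from_edges(20, list(g.edges))
        gamma, lam, sigma = small_world_indices(adj, [adj])
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_random_graph_sigma_near_one(self):
        g = nx.gnp_random_graph(90, 0.11, seed=7)
        adj = adjacency_from_edges(90, list(g.edges))
        c_p, _ = clustering_coefficient(adj)
        l_p = characteristic_path_length_harmonic(adj)
        cp_null, lp_null = null_cp_lp_means(adj, 100, seed=11)
        sigma = (c_p / cp_null) / (l_p / lp_null)
        assert 0.8 < sigma < 1.2

    def test_sigma_equals_gamma_over_lambda(self):
        g = nx.watts_strogatz_graph(30, 6, 0.1, seed=6)
        adj = adjacency_from_edges(30, list(g.edges))
        nulls = random_null_ensemble(adj, 10, seed=2)
        gamma, lam, sigma = small_world_indices(adj, nulls)
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)


class TestAuc:
    def test_constant_curve(self):
        grid = sparsity_grid()
        assert auc_over_grid(np.full(36, 2.5), grid) == pytest.approx(2.5 * 0.35)

    def test_linear_curve_exact(self):
        grid = sparsity_grid()
        values = 3.0 * grid.values + 1.0
        expected = 1.5 * (0.40**2 - 0.05**2) + 1.0 * 0.35
        assert auc_over_grid(values, grid) == pytest.approx(expected, abs=1e-12)

    def test_two_point_trapezoid(self):
        grid = sparsity_grid(0.1, 0.2, 0.1)
        assert auc_over_grid([1.0, 3.0], grid) == pytest.approx(0.2)

    def test_nonfinite_propagates_sentinel(self):
        grid = sparsity_grid(0.1, 0.2, 0.1)
        with pytest.warns(UserWarning, match="non-finite"):
            assert auc_over_grid([1.0, np.inf], grid) == np.inf
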