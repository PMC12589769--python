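"""Centrality descriptors against independent oracles.

The package computes every centrality directly on the adjacency matrix; the
oracles here re-derive them from first principles (Floyd-Warshall distances,
walk-counting for shortest-path multiplicities, a dense linear solve for
PageRank) or through networkx.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from meagdn import graph_descriptors as gd
from meagdn.errors import DataError

from conftest import random_digraph


# ---------------------------------------------------------------------------
# brute-force oracles


def floyd_warshall(A):
    n = A.shape[0]
    D = np.where(A, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                D[i, j] = min(D[i, j], D[i, k] + D[k, j])
    return D


def path_counts(A, D):
    """sigma[j, k]: number of shortest j->k paths, via walk counting (every
    walk whose length equals the geodesic distance is a shortest path)."""
    n = A.shape[0]
    sigma = np.zeros((n, n))
    P = np.eye(n)
    M = A.astype(float)
    maxd = int(D[np.isfinite(D)].max()) if np.isfinite(D).any() else 0
    powers = [P]
    for _ in range(maxd):
        P = P @ M
        powers.append(P)
    for j in range(n):
        for k in range(n):
            if np.isfinite(D[j, k]):
                sigma[j, k] = powers[int(D[j, k])][j, k]
    return sigma


def betweenness_oracle(A):
    D = floyd_warshall(A)
    sigma = path_counts(A, D)
    n = A.shape[0]
    bc = np.zeros(n)
    for i, j, k in itertools.product(range(n), repeat=3):
        if i == j or i == k or j == k:
            continue
        if np.isfinite(D[j, k]) and D[j, i] + D[i, k] == D[j, k]:
            bc[i] += sigma[j, i] * sigma[i, k] / sigma[j, k]
    return bc


def pagerank_oracle(A, d=0.85):
    """Dense linear solve of the damped fixed point with uniform dangling
    redistribution."""
    n = A.shape[0]
    out = A.sum(axis=1)
    M = np.zeros((n, n))
    for i in range(n):
        if out[i]:
            M[:, i] = A[i] / out[i]
        else:
            M[:, i] = 1.0 / n
    pr = np.linalg.solve(np.eye(n) - d * M, np.full(n, (1 - d) / n))
    return pr / pr.sum()


# ---------------------------------------------------------------------------
# hand-derivable fixtures


def cycle(n):
    A = np.zeros((n, n), dtype=bool)
    for i in range(n):
        A[i, (i + 1) % n] = True
    return A


def complete(n):
    A = np.ones((n, n), dtype=bool)
    np.fill_diagonal(A, False)
    return A


class TestHandValues:
    def test_cycle_degrees_are_uniform(self):
        s = gd.degree_stats(cycle(4))
        assert s["mean_indegree"] == 1 and s["std_indegree"] == 0
        assert s["mean_outdegree"] == 1 and s["std_outdegree"] == 0

    def test_complete_graph_indegree(self):
        s = gd.degree_stats(complete(4))
        assert s["min_indegree"] == s["max_indegree"] == 3

    def test_leaf_to_hub_star_degree_extremes(self):
        A = np.zeros((4, 4), dtype=bool)
        A[1:, 0] = True  # leaves -> hub
        s = gd.degree_stats(A)
        assert s["max_indegree"] == 3 and s["min_indegree"] == 0

    def test_complete_graph_incloseness(self):
        in_c, out_c = gd.closeness_values(complete(4))
        assert np.allclose(in_c, 1 / 3) and np.allclose(out_c, 1 / 3)

    def test_cycle_outcloseness(self):
        _, out_c = gd.closeness_values(cycle(4))
        assert np.allclose(out_c, 1 / 6)

    def test_isolated_node_closeness_is_zero(self):
        A = np.zeros((3, 3), dtype=bool)
        A[0, 1] = True
        in_c, out_c = gd.closeness_values(A)
        assert in_c[2] == 0 and out_c[2] == 0

    def test_path_betweenness(self):
        A = np.zeros((3, 3), dtype=bool)
        A[0, 1] = A[1, 2] = True  # a -> b -> c
        assert np.allclose(gd.betweenness_values(A), [0, 1, 0])

    def test_complete_graph_betweenness_zero(self):
        assert np.allclose(gd.betweenness_values(complete(4)), 0)

    def test_cycle_betweenness(self):
        # in the directed 4-cycle each node is interior to the unique
        # shortest paths of 3 ordered pairs: one 2-step and two 3-step
        assert np.allclose(gd.betweenness_values(cycle(4)), 3)

    def test_cycle_pagerank_uniform(self):
        assert np.allclose(gd.pagerank_values(cycle(5)), 1 / 5)

    def test_two_node_chain_pagerank(self):
        A = np.zeros((2, 2), dtype=bool)
        A[0, 1] = True
        pr = gd.pagerank_values(A)
        assert pr[1] > pr[0]
        assert np.allclose(pr, pagerank_oracle(A), atol=1e-8)

    def test_star_hits(self):
        A = np.zeros((4, 4), dtype=bool)
        A[1:, 0] = True
        h, a = gd.hits_values(A)
        assert np.allclose(a, [1, 0, 0, 0])
        assert np.allclose(h, [0, 1 / 3, 1 / 3, 1 / 3])

    def test_cycle_hits_uniform(self):
        h, a = gd.hits_values(cycle(4))
        assert np.allclose(h, 1 / 4) and np.allclose(a, 1 / 4)

    def test_bipartite_hits(self):
        A = np.zeros((4, 4), dtype=bool)
        A[0, 2] = A[0, 3] = A[1, 2] = A[1, 3] = True
        h, a = gd.hits_values(A)
        assert np.allclose(h, [0.5, 0.5, 0, 0])
        assert np.allclose(a, [0, 0, 0.5, 0.5])

    def test_complete_graph_global(self):
        g = gd.global_stats(complete(4))
        assert g["cpl"] == 1 and g["diameter"] == 1 and g["global_efficiency"] == 1

    def test_cycle_global(self):
        g = gd.global_stats(cycle(4))
        assert g["cpl"] == 2 and g["diameter"] == 3
        assert np.isclose(g["global_efficiency"], 11 / 18)

    def test_empty_graph_global(self):
        g = gd.global_stats(np.zeros((4, 4), dtype=bool))
        assert np.isnan(g["cpl"]) and np.isnan(g["diameter"])
        assert g["global_efficiency"] == 0


class TestOracles:
    """Dual-route checks on random digraphs."""

    @pytest.mark.parametrize("n,p,seed", [(5, 0.3, 0), (8, 0.2, 1), (8, 0.5, 2),
                                          (16, 0.15, 3), (16, 0.4, 4)])
    def test_betweenness_matches_networkx(self, n, p, seed):
        A = random_digraph(n, p, np.random.default_rng(seed))
        G = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
        expected = nx.betweenness_centrality(G, normalized=False)
        got = gd.betweenness_values(A)
        assert np.allclose(got, [expected[i] for i in range(n)])

    @pytest.mark.parametrize("n,p,seed", [(6, 0.3, 0), (16, 0.2, 1), (16, 0.5, 2)])
    def test_pagerank_matches_networkx(self, n, p, seed):
        A = random_digraph(n, p, np.random.default_rng(seed))
        G = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
        expected = nx.pagerank(G, alpha=0.85, tol=1e-12, max_iter=1000)
        got = gd.pagerank_values(A)
        assert np.allclose(got, [expected[i] for i in range(n)], atol=1e-8)

    @pytest.mark.parametrize("n,p,seed", [(6, 0.4, 0), (16, 0.3, 1)])
    def test_hits_matches_networkx(self, n, p, seed):
        A = random_digraph(n, p, np.random.default_rng(seed))
        if not A.any():
            pytest.skip("edgeless draw")
        G = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
        eh, ea = nx.hits(G, max_iter=1000, tol=1e-12)
        h, a = gd.hits_values(A, tol=1e-12)
        assert np.allclose(h, [eh[i] for i in range(n)], atol=1e-6)
        assert np.allclose(a, [ea[i] for i in range(n)], atol=1e-6)

    @pytest.mark.parametrize("n,p,seed", [(5, 0.3, 0), (16, 0.25, 1)])
    def test_distances_match_floyd_warshall(self, n, p, seed):
        A = random_digraph(n, p, np.random.default_rng(seed))
        assert np.array_equal(gd.distance_matrix(A), floyd_warshall(A))

    @pytest.mark.parametrize("seed", range(3))
    def test_betweenness_matches_path_enumeration(self, seed):
        A = random_digraph(6, 0.35, np.random.default_rng(seed + 10))
        assert np.allclose(gd.betweenness_values(A), betweenness_oracle(A))


class TestAssembly:
    def test_full_vector_has_35_named_scalars(self):
        vec = gd.descriptor_vector(complete(4))
        assert len(vec) == 35 and tuple(vec) == gd.FULL_35

    def test_retained_list_has_19_names(self):
        assert len(gd.RETAINED_19) == 19
        assert set(gd.RETAINED_19) <= set(gd.FULL_35)

    def test_pagerank_sums_to_one_and_ds_bounds_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = random_digraph(16, rng.uniform(0.05, 0.6), rng)
            assert np.isclose(gd.pagerank_values(A).sum(), 1.0)

    def test_excluded_descriptor_means_are_constant(self):
        """Mean PageRank/hub/authority are fixed by their sum normalization,
        which is the stated reason they are excluded from the retained set."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = random_digraph(8, 0.3, rng)
            if not A.any():
                continue
            vec = gd.descriptor_vector(A)
            assert np.isclose(vec["mean_pagerank"], 1 / 8)
            assert np.isclose(vec["mean_hubrank"], 1 / 8)
            assert np.isclose(vec["mean_authrank"], 1 / 8)

    def test_descriptors_invariant_to_node_relabeling(self):
        rng = np.random.default_rng(2)
        A = random_digraph(7, 0.35, rng)
        perm = rng.permutation(7)
        B = A[np.ix_(perm, perm)]
        va, vb = gd.descriptor_vector(A), gd.descriptor_vector(B)
        for name in gd.FULL_35:
            assert np.isclose(va[name], vb[name], equal_nan=True), name

    def test_timeseries_rows_and_metadata(self):
        from meagdn.gdn_model import GraphSnapshot

        rng = np.random.default_rng(3)
        snaps = []
        for t in range(5):
            A = random_digraph(4, 0.4, rng)
            snaps.append(GraphSnapshot(alpha=np.full((4, 4), 0.25), adjacency=A,
                                       time_index=t + 1, segment_id=0))
        series = gd.descriptor_timeseries(snaps, well_id="B1", session="24h",
                                          condition="CTRL")
        assert len(series.table) == 5
        assert series.retained.shape[1] == 19 + len(
            [c for c in gd.METADATA_COLUMNS if c in series.table.columns])
        assert set(gd.FULL_35) <= set(series.full.columns)

    def test_self_loop_rejected(self):
        A = np.eye(3, dtype=bool)
        with pytest.raises(DataError):
            gd.descriptor_vector(A)
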