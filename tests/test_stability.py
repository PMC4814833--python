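"""Markov stability identities, Louvain optimisation and time sweeps."""

from itertools import product

import numpy as np
import pytest

from memflow import (
    DirectedGraph,
    Partition,
    flow_modularity_matrix,
    linearized_stability,
    markov_stability,
    optimize_partition,
    stationary_distribution,
    sweep_markov_time,
)
from memflow.graph_core import GraphError
from tests.conftest import random_connected_graph


def newman_girvan_modularity(g: DirectedGraph, labels: np.ndarray) -> float:
    """Textbook modularity oracle: Q = sum_C [ e_C/m - (d_C/2m)^2 ]."""
    A = g.A.toarray()
    two_m = A.sum()
    k = A.sum(axis=1)
    Q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        Q += A[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return Q


def random_partition(rng, n, k):
    labels = rng.integers(0, k, size=n)
    labels[rng.permutation(n)[:k]] = np.arange(k)  # no empty community
    return labels


class TestStabilityIdentities:
    @pytest.mark.parametrize("t", [0.0, 0.5, 1.0, 4.0])
    def test_all_in_one_partition_is_zero(self, two_cliques, t):
        p = Partition(np.zeros(two_cliques.N, dtype=int))
        assert markov_stability(two_cliques, p, t) == pytest.approx(0.0, abs=1e-12)
        assert linearized_stability(two_cliques, p, t) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_partition_at_time_zero(self, two_cliques):
        pi = stationary_distribution(two_cliques)
        p = Partition(np.arange(two_cliques.N))
        expected = 1 - np.sum(pi**2)
        assert markov_stability(two_cliques, p, 0.0) == pytest.approx(expected, abs=1e-12)
        assert linearized_stability(two_cliques, p, 0.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("t", [0.25, 1.0, 3.0])
    def test_two_node_closed_form(self, t):
        g = DirectedGraph.from_edges([(0, 1)], undirected=True)
        p = Partition([0, 1])
        assert markov_stability(g, p, t) == pytest.approx(np.exp(-2 * t) / 2, abs=1e-12)

    def test_linearized_matches_full_at_time_zero(self, two_cliques):
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = Partition(random_partition(rng, two_cliques.N, 3))
            assert linearized_stability(two_cliques, p, 0.0) == pytest.approx(
                markov_stability(two_cliques, p, 0.0), abs=1e-12
            )

    def test_long_time_flow_approaches_independence(self, triangle):
        fm = flow_modularity_matrix(triangle, 1e3)
        pi = fm.pi
        assert np.allclose(fm.Y, np.outer(pi, pi), atol=1e-10)


class TestModularityEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_linearized_t1_equals_newman_girvan(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, n=rng.integers(5, 10), weighted=True)
        for k in (2, 3):
            labels = random_partition(rng, g.N, k)
            assert linearized_stability(g, Partition(labels), 1.0) == pytest.approx(
                newman_girvan_modularity(g, labels), abs=1e-10
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_stability_equals_modularity_of_flow_network(self, seed):
        # R(t) == modularity of Y(t) under the pi_i*pi_j null, any partition
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, n=6)
        fm = flow_modularity_matrix(g, 0.8)
        for _ in range(4):
            p = Partition(random_partition(rng, g.N, 3))
            q_direct = markov_stability(g, p, 0.8)
            B = fm.Y - np.outer(fm.pi, fm.pi)
            q_flow = sum(B[np.ix_(c, c)].sum() for c in p.communities())
            assert q_direct == pytest.approx(q_flow, abs=1e-10)

    def test_disconnected_triangles_modularity_half(self):
        # two triangles, teleport smoothing: optimum partition has Q ~ 0.5
        g = DirectedGraph.from_edges(
            [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)], undirected=True
        )
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert newman_girvan_modularity(g, labels) == pytest.approx(0.5)
        from memflow import ensure_ergodic

        g2, _ = ensure_ergodic(g, strategy="teleport", teleport_rate=0.01)
        q = linearized_stability(g2, Partition(labels), 1.0)
        assert q == pytest.approx(0.5, abs=0.02)


class TestLouvain:
    def test_two_cliques_recovered_and_match_exhaustive_search(self, two_cliques):
        fm = flow_modularity_matrix(two_cliques, 1.0)
        part, value = optimize_partition(fm, n_runs=10, seed=0)
        assert part.n_communities == 2
        assert len(set(part.labels[:4])) == 1 and len(set(part.labels[4:])) == 1
        # exhaustive bipartition search confirms the optimum
        best = -np.inf
        for bits in product([0, 1], repeat=two_cliques.N - 1):
            labels = np.array((0,) + bits)
            best = max(best, fm.quality(Partition(labels)))
        assert value == pytest.approx(best, abs=1e-12)

    def test_ring_of_four_triangles_at_small_time(self):
        # four 3-cliques joined into a ring by single edges
        edges = []
        for k in range(4):
            a, b, c = 3 * k, 3 * k + 1, 3 * k + 2
            edges += [(a, b), (b, c), (a, c), (c, (3 * (k + 1)) % 12)]
        g = DirectedGraph.from_edges(edges, undirected=True)
        part, _ = optimize_partition(flow_modularity_matrix(g, 0.3), n_runs=10, seed=1)
        assert part.n_communities == 4
        for k in range(4):
            assert len(set(part.labels[3 * k : 3 * k + 3])) == 1

    def test_louvain_beats_trivial_partitions(self, two_cliques):
        for t in (0.3, 1.0, 3.0):
            fm = flow_modularity_matrix(two_cliques, t)
            _, value = optimize_partition(fm, n_runs=5, seed=2)
            assert value >= fm.quality(Partition(np.zeros(8, dtype=int))) - 1e-12
            assert value >= fm.quality(Partition(np.arange(8))) - 1e-12

    def test_stationarity_limit_collapses_to_few_communities(self, two_cliques):
        part, _ = optimize_partition(
            flow_modularity_matrix(two_cliques, 1e3), n_runs=5, seed=3
        )
        assert part.n_communities <= 2

    def test_deterministic_under_seed(self, two_cliques):
        fm = flow_modularity_matrix(two_cliques, 1.0)
        p1, v1 = optimize_partition(fm, n_runs=5, seed=42)
        p2, v2 = optimize_partition(fm, n_runs=5, seed=42)
        assert np.array_equal(p1.labels, p2.labels) and v1 == v2

    def test_invalid_run_count(self, two_cliques):
        with pytest.raises(GraphError, match="n_runs"):
            optimize_partition(flow_modularity_matrix(two_cliques, 1.0), n_runs=0)


class TestSweep:
    def test_two_clique_plateau(self, two_cliques):
        curve = sweep_markov_time(
            two_cliques, np.logspace(-1, 1, 20), n_runs=5, seed=0
        )
        counts = curve.community_counts()
        vis = np.asarray([e.run_vi for e in curve.entries])
        plateau = (counts == 2) & (vis == 0.0)
        # a run of >= 3 consecutive robust 2-community points
        best_run, run = 0, 0
        for ok in plateau:
            run = run + 1 if ok else 0
            best_run = max(best_run, run)
        assert best_run >= 3
        assert curve.plateaux(vi_threshold=0.05, min_len=3)

    def test_community_count_coarsens_with_time(self, two_cliques):
        curve = sweep_markov_time(
            two_cliques, np.logspace(-1, 1, 10), n_runs=5, seed=1
        )
        counts = curve.community_counts()
        assert np.all(np.diff(counts) <= 0)

    def test_empty_grid_rejected(self, two_cliques):
        with pytest.raises(GraphError, match="grid"):
            sweep_markov_time(two_cliques, [], n_runs=2, seed=0)
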