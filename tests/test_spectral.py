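"""Non-backtracking operators, spectral bipartition, detectability limit."""

import numpy as np
import pytest

from memflow import (
    DirectedGraph,
    SBMConfig,
    build_memory_state_space,
    decompose_line_graph,
    detectability_threshold,
    generate_sbm_bipartition,
    nonbacktracking_matrix,
    nonbacktracking_transition,
    spectral_bipartition,
)
from memflow.graph_core import GraphError
from memflow.spectral import two_core
from tests.conftest import random_connected_graph


class TestNonbacktrackingMatrix:
    def test_triangle_unique_continuation(self, triangle):
        B, m = nonbacktracking_matrix(triangle)
        assert np.all(np.asarray(B.sum(axis=1)).ravel() == 1)

    def test_path_end_state_has_no_continuation(self, path3):
        # arriving at an endpoint, the only way on is back: (2->3) and
        # (2->1) have empty non-backtracking rows, (1->2) has exactly one
        B, m = nonbacktracking_matrix(path3)
        i = path3.index_of
        rows = np.asarray(B.sum(axis=1)).ravel()
        assert rows[m.state_index[(i(2), i(3))]] == 0
        assert rows[m.state_index[(i(2), i(1))]] == 0
        assert rows[m.state_index[(i(1), i(2))]] == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_triangular_plus_exploratory(self, seed):
        g = random_connected_graph(np.random.default_rng(seed))
        B, _ = nonbacktracking_matrix(g)
        d = decompose_line_graph(g)
        assert ((B != (d.G_tri + d.G_exp).astype(float)).nnz) == 0

    def test_leading_eigenvalue_on_regular_graph(self):
        # on a c-regular graph the Perron eigenvalue of B is c - 1
        edges = [(i, j) for i in range(6) for j in range(i + 1, 6)
                 if (j - i) in (1, 5) or (j - i) == 3]  # K_{3,3}-like 3-regular
        g = DirectedGraph.from_edges(edges, undirected=True)
        assert np.all(g.degree == 3)
        B, _ = nonbacktracking_matrix(g)
        lead = max(np.linalg.eigvals(B.toarray()).real)
        assert lead == pytest.approx(2.0, abs=1e-9)


class TestNonbacktrackingTransition:
    def test_triangle_rows_already_stochastic(self, triangle):
        B, _ = nonbacktracking_matrix(triangle)
        m = nonbacktracking_transition(triangle)
        assert np.allclose(m.T.toarray(), B.toarray())

    def test_degree_three_rows_split_evenly(self):
        g = DirectedGraph.from_edges(
            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)], undirected=True
        )
        m = nonbacktracking_transition(g)
        data = m.T.tocoo().data
        assert np.allclose(data, 0.5)

    def test_dangling_state_named_in_error(self, path3):
        with pytest.raises(GraphError, match="non-backtracking continuation"):
            nonbacktracking_transition(path3)

    def test_two_core_restriction_resolves_dangling(self, triangle):
        g = DirectedGraph.from_edges(
            [(1, 2), (2, 3), (3, 1), (3, 4)], undirected=True
        )
        m = nonbacktracking_transition(g, drop_dangling=True)
        assert m.n_states == 6  # only the triangle survives


class TestSpectralBipartition:
    def test_disconnected_cliques_exact_recovery(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        g = DirectedGraph.from_edges(edges, undirected=True)
        m = nonbacktracking_transition(g)
        planted = np.array([1] * 5 + [-1] * 5)
        res = spectral_bipartition(m.T, g, states=m.states, planted=planted)
        assert res.nmi == 1.0

    def test_sign_flip_leaves_partition_unchanged(self):
        rng = np.random.default_rng(0)
        score = rng.normal(size=10)
        g1 = np.where(score > 0, 1, -1)
        g2 = np.where(-score > 0, 1, -1)
        from memflow.partition_metrics import normalized_mutual_information
        from memflow import Partition

        assert (
            normalized_mutual_information(
                Partition((g1 > 0).astype(int)), Partition((g2 > 0).astype(int))
            )
            == 1.0
        )

    def test_dimension_mismatch_rejected(self, triangle):
        m = build_memory_state_space(triangle)
        with pytest.raises(GraphError, match="dimension"):
            spectral_bipartition(np.eye(4), triangle, states=m.states)

    def test_node_space_operator(self):
        # adjacency of two loosely joined cliques: second eigenvector
        # separates them directly in node space
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        edges += [(0, 4)]
        g = DirectedGraph.from_edges(edges, undirected=True)
        planted = np.array([1] * 4 + [-1] * 4)
        res = spectral_bipartition(g.A.toarray(), g, planted=planted)
        assert res.nmi == 1.0


class TestDetectabilityThreshold:
    def test_printed_value_at_ratio_0_3(self):
        assert detectability_threshold(0.3) == pytest.approx(3.449, abs=5e-4)

    def test_disjoint_groups_limit(self):
        assert detectability_threshold(0.0) == pytest.approx(1.0)

    def test_monotone_increasing_and_diverging(self):
        grid = np.linspace(0.0, 0.95, 20)
        vals = [detectability_threshold(r) for r in grid]
        assert np.all(np.diff(vals) > 0)
        assert detectability_threshold(0.99) > 1e3

    def test_equal_groups_rejected(self):
        with pytest.raises(GraphError, match="undetectable"):
            detectability_threshold(1.0)


class TestSBMGenerator:
    def test_mean_degree_concentrates(self):
        degs = []
        for seed in range(5):
            g, _ = generate_sbm_bipartition(SBMConfig(N=2000, c=8, ratio=0.3,
                                                      seed=seed))
            degs.append(g.A.sum() / g.N)
        assert np.mean(degs) == pytest.approx(8.0, abs=0.3)

    def test_between_within_ratio(self):
        g, labels = generate_sbm_bipartition(
            SBMConfig(N=4000, c=10, ratio=0.3, seed=1)
        )
        A = g.A
        half = g.N // 2
        within = A[:half][:, :half].sum() + A[half:][:, half:].sum()
        between = A[:half][:, half:].sum() + A[half:][:, :half].sum()
        assert between / within == pytest.approx(0.3, rel=0.1)

    def test_zero_ratio_disconnects_groups(self):
        g, labels = generate_sbm_bipartition(SBMConfig(N=200, c=6, ratio=0.0,
                                                       seed=2))
        half = g.N // 2
        assert g.A[:half][:, half:].sum() == 0

    def test_overdense_parameters_rejected(self):
        with pytest.raises(GraphError, match="probabilities"):
            generate_sbm_bipartition(SBMConfig(N=10, c=9, ratio=0.0, seed=0))

    def test_odd_node_count_rejected(self):
        with pytest.raises(GraphError, match="even"):
            SBMConfig(N=11, c=4, ratio=0.3)


class TestMemoryInterpolation:
    def test_low_return_weight_tracks_nonbacktracking_performance(self):
        # clustering with r2 -> 0 should not trail the equal-parameter
        # (first-order-like) operator at moderate degree
        from memflow import MemoryParameters, model_transition_matrix

        nmis = {0.01: [], 1.0: []}
        for seed in range(6):
            g, labels = generate_sbm_bipartition(
                SBMConfig(N=1000, c=6, ratio=0.3, seed=seed)
            )
            core, idx = two_core(g)
            lab = labels[idx]
            d = decompose_line_graph(core)
            for r2 in nmis:
                m = model_transition_matrix(d, MemoryParameters(r2, 1.0, 1.0))
                res = spectral_bipartition(m.T, core, states=m.states,
                                           planted=lab)
                nmis[r2].append(res.nmi)
        assert np.mean(nmis[0.01]) >= np.mean(nmis[1.0]) - 0.05
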