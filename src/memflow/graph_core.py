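"""Base graphs, memory-network state spaces and pathway data.

A second-order random walk on a graph is a first-order walk on the
*memory network*: its states are the directed edges of the base graph, and
a state (i, j) may only be followed by states (j, k) — the structure of a
directed line graph.  This module builds those state spaces and populates
their transition weights either by lifting the first-order walk or by
counting consecutive edge pairs (trigrams) in empirical pathway data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DirectedGraph",
    "MemoryNetwork",
    "PathwaySet",
    "build_memory_state_space",
    "lift_first_order",
    "build_m2_from_pathways",
    "project_to_nodes",
]


class GraphError(ValueError):
    """Raised for structurally invalid graph or pathway input."""


@dataclass
class DirectedGraph:
    """A weighted directed graph with opaque node labels.

    Parameters
    ----------
    node_ids:
        Ordered node labels; internal indices are their positions.
    A:
        Nonnegative weighted adjacency, ``A[i, j]`` = weight of link i->j.
        Stored as CSR.  An undirected graph is represented by a symmetric
        matrix (each undirected edge appears in both directions).
    undirected:
        Declares the graph undirected; asserts ``A`` symmetric.
    """

    node_ids: list
    A: sp.csr_array
    undirected: bool = False

    def __post_init__(self) -> None:
        self.A = sp.csr_array(self.A)
        self.A.eliminate_zeros()
        n = len(self.node_ids)
        if n < 1:
            raise GraphError("graph must have at least one node")
        if self.A.shape != (n, n):
            raise GraphError(
                f"adjacency shape {self.A.shape} does not match {n} nodes"
            )
        if self.A.nnz and self.A.data.min() < 0:
            raise GraphError("edge weights must be nonnegative")
        if self.undirected and (abs(self.A - self.A.T)).sum() > 1e-12 * max(self.W, 1.0):
            raise GraphError("undirected graph requires a symmetric adjacency")
        self._index = {v: i for i, v in enumerate(self.node_ids)}

    # -- derived quantities -------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.node_ids)

    @property
    def M(self) -> int:
        """Edge count: directed edges, or undirected edges when symmetric."""
        nnz = self.A.nnz
        return nnz // 2 if self.undirected else nnz

    @property
    def W(self) -> float:
        """Total weight of the adjacency (both directions for undirected)."""
        return float(self.A.sum())

    @property
    def out_degree(self) -> np.ndarray:
        """Weighted out-degree k_j^out."""
        return np.asarray(self.A.sum(axis=1)).ravel()

    @property
    def degree(self) -> np.ndarray:
        """Node strength; equals the degree k_j for an undirected graph."""
        if self.undirected:
            return self.out_degree
        return np.asarray(self.A.sum(axis=1)).ravel() + np.asarray(
            self.A.sum(axis=0)
        ).ravel()

    def index_of(self, node) -> int:
        return self._index[node]

    def edges(self) -> list[tuple[int, int, float]]:
        coo = self.A.tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable] | tuple[Hashable, Hashable, float]],
        undirected: bool = False,
        node_ids: Sequence | None = None,
    ) -> "DirectedGraph":
        """Build a graph from (src, dst[, weight]) tuples.

        Duplicate edges have their weights summed; for an undirected graph
        each input edge is mirrored.
        """
        rows: list = []
        cols: list = []
        data: list[float] = []
        order: dict = {}
        if node_ids is not None:
            for v in node_ids:
                order.setdefault(v, len(order))
        for e in edges:
            u, v = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            for x in (u, v):
                if x not in order:
                    order[x] = len(order)
            rows.append(order[u])
            cols.append(order[v])
            data.append(w)
            if undirected and u != v:
                rows.append(order[v])
                cols.append(order[u])
                data.append(w)
        n = len(order)
        A = sp.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()
        A.sum_duplicates()
        return cls(list(order), A, undirected=undirected)


@dataclass
class MemoryNetwork:
    """State space of ordered node pairs (directed edges) of a base graph.

    ``states[a] = (i, j)`` (internal node indices).  ``G`` is the boolean
    directed-line-graph structure: ``G[a, b] = 1`` iff state b continues
    state a (b's source equals a's target).  ``weights`` and ``T`` hold
    state-to-state transition weights and the row-normalised transition
    matrix once populated.
    """

    states: list[tuple[int, int]]
    base: DirectedGraph
    G: sp.csr_array
    weights: sp.csr_array | None = None
    T: sp.csr_array | None = None
    kind_tag: str = "unset"
    state_index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.state_index:
            self.state_index = {s: a for a, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_labels(self) -> list[tuple]:
        ids = self.base.node_ids
        return [(ids[i], ids[j]) for i, j in self.states]

    def state_weight(self) -> np.ndarray:
        """w_alpha: the base-edge weight of each state."""
        coo = self.base.A.tocoo()
        lut = {(i, j): w for i, j, w in zip(coo.row, coo.col, coo.data)}
        return np.asarray([lut.get(s, 0.0) for s in self.states], dtype=float)

    def out_strength(self) -> np.ndarray:
        """s_alpha^out under the current transition weights."""
        if self.weights is None:
            raise GraphError("memory network has no transition weights yet")
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def set_weights(self, W: sp.csr_array, kind_tag: str) -> None:
        W = sp.csr_array(W)
        bad = (W.multiply(self.G) - W).sum()
        if abs(bad) > 1e-12:
            raise GraphError("transition weights outside the line-graph structure")
        self.weights = W
        self.T = _row_normalise(W, strict=False)
        self.kind_tag = kind_tag

    def dangling_states(self) -> np.ndarray:
        """Indices of states with zero out-weight (or zero structure)."""
        mat = self.weights if self.weights is not None else self.G
        s = np.asarray(mat.sum(axis=1)).ravel()
        return np.flatnonzero(s <= 0)


@dataclass
class PathwaySet:
    """Multiset of node sequences (trajectories) with multiplicities."""

    paths: list[tuple[list, int]]

    def __post_init__(self) -> None:
        for seq, mult in self.paths:
            if len(seq) < 2:
                raise GraphError("every pathway needs at least two nodes")
            if mult < 1:
                raise GraphError("pathway multiplicities must be >= 1")

    @property
    def n_paths(self) -> int:
        return sum(m for _, m in self.paths)

    def n_transitions(self) -> int:
        """Number of edge-to-edge (triple) transitions, with multiplicity."""
        return sum(max(len(seq) - 2, 0) * m for seq, m in self.paths)

    def validate_against(self, g: DirectedGraph) -> None:
        coo = g.A.tocoo()
        edge_set = set(zip(coo.row.tolist(), coo.col.tolist()))
        for seq, _ in self.paths:
            idx = [g.index_of(v) for v in seq]
            for u, v in zip(idx[:-1], idx[1:]):
                if (u, v) not in edge_set:
                    raise GraphError(
                        f"pathway step {g.node_ids[u]}->{g.node_ids[v]} "
                        "is not an edge of the base graph"
                    )


# ---------------------------------------------------------------------------


def _row_normalise(W: sp.csr_array, strict: bool = True) -> sp.csr_array:
    W = sp.csr_array(W, dtype=float)
    s = np.asarray(W.sum(axis=1)).ravel()
    if strict and np.any(s <= 0):
        raise GraphError("row normalisation hit a state with zero out-weight")
    inv = np.divide(1.0, s, out=np.zeros_like(s), where=s > 0)
    return sp.csr_array(sp.diags_array(inv) @ W)


def _line_graph_structure(
    states: list[tuple[int, int]], n_nodes: int
) -> sp.csr_array:
    """Boolean directed-line-graph adjacency over ``states``."""
    n = len(states)
    src = np.fromiter((s[0] for s in states), dtype=np.int64, count=n)
    tgt = np.fromiter((s[1] for s in states), dtype=np.int64, count=n)
    # successors of state a are the states whose source is a's target
    order = np.argsort(src, kind="stable")
    bounds = np.searchsorted(src[order], np.arange(n_nodes + 1))
    counts = bounds[tgt + 1] - bounds[tgt]
    rows = np.repeat(np.arange(n), counts)
    cols = np.concatenate(
        [order[bounds[t] : bounds[t + 1]] for t in tgt]
    ) if n else np.empty(0, dtype=np.int64)
    data = np.ones(rows.shape[0], dtype=np.int8)
    return sp.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()


def build_memory_state_space(g: DirectedGraph) -> MemoryNetwork:
    """Create the (unweighted) memory state space of a graph.

    One state per directed edge — two per undirected edge — connected as a
    directed line graph.  Weights and the transition matrix are left unset.
    """
    coo = g.A.tocoo()
    if coo.nnz == 0:
        raise GraphError("no edges: cannot build a memory state space")
    states = sorted(zip(coo.row.tolist(), coo.col.tolist()))
    G = _line_graph_structure(states, g.N)
    return MemoryNetwork(states=states, base=g, G=G)


def lift_first_order(g: DirectedGraph) -> MemoryNetwork:
    """Lift the first-order walk onto the edge state space (M1ext).

    The transition from state alpha=(i, j) to beta=(j, k) is proportional
    to the base weight w_beta = A[j, k]; the normaliser s_alpha^out is the
    out-strength of the shared node j.  Projecting the lifted walk back to
    nodes reproduces the first-order walk exactly, and on an undirected
    base the stationary distribution is pi_alpha = w_alpha / W.
    """
    m = build_memory_state_space(g)
    w = m.state_weight()
    # weight of transition a->b is the base weight of edge b
    W = sp.csr_array(m.G.astype(float) @ sp.diags_array(w))
    out = np.asarray(W.sum(axis=1)).ravel()
    if np.any(out <= 0):
        a = int(np.flatnonzero(out <= 0)[0])
        i, j = m.states[a]
        raise GraphError(
            f"dangling memory state ({g.node_ids[i]}->{g.node_ids[j]}): "
            f"node {g.node_ids[j]} has no outgoing edge; run ensure_ergodic first"
        )
    m.set_weights(W, kind_tag="M1ext")
    return m


def build_m2_from_pathways(
    paths: PathwaySet,
    g: DirectedGraph | None = None,
    pseudocount: float = 0.0,
) -> MemoryNetwork:
    """Estimate a second-order (M2) transition matrix from pathway data.

    Counts consecutive node triples (i, j, k) across all pathways
    (overlapping trigrams, weighted by multiplicity) as transitions from
    memory state (i, j) to (j, k), then row-normalises.  The state space
    is restricted to the edges observed in the data, or to the edges of
    ``g`` when a base graph is supplied.  ``pseudocount`` adds a uniform
    prior mass on line-graph-admissible successors only.
    """
    if pseudocount < 0:
        raise GraphError("pseudocount must be nonnegative")
    if g is not None:
        paths.validate_against(g)
        base = g
    else:
        edges: dict[tuple, float] = {}
        for seq, mult in paths.paths:
            for u, v in zip(seq[:-1], seq[1:]):
                edges[(u, v)] = edges.get((u, v), 0.0) + mult
        base = DirectedGraph.from_edges(
            [(u, v, w) for (u, v), w in edges.items()]
        )
    m = build_memory_state_space(base)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for seq, mult in paths.paths:
        if len(seq) < 3:
            continue
        idx = np.asarray([base.index_of(v) for v in seq], dtype=np.int64)
        a = np.asarray(
            [m.state_index[(i, j)] for i, j in zip(idx[:-2], idx[1:-1])],
            dtype=np.int64,
        )
        b = np.asarray(
            [m.state_index[(i, j)] for i, j in zip(idx[1:-1], idx[2:])],
            dtype=np.int64,
        )
        rows.append(a)
        cols.append(b)
        vals.append(np.full(a.shape[0], float(mult)))
    if not rows or sum(r.size for r in rows) == 0:
        raise GraphError(
            "no edge-to-edge transition observed: need a pathway of length >= 3"
        )
    n = m.n_states
    C = sp.coo_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    if pseudocount > 0:
        C = sp.csr_array(C + pseudocount * m.G.astype(float))
    m.set_weights(C, kind_tag="M2_empirical")
    return m


def project_to_nodes(m: MemoryNetwork, pi: np.ndarray) -> DirectedGraph:
    """Project a stationary memory walk down to node-to-node flows.

    Returns a graph whose adjacency is the flow matrix
    ``F[j, k] = sum_i pi[(i,j)] T[(i,j),(j,k)]``; F sums to one.
    """
    if m.T is None:
        raise GraphError("memory network has no transition matrix")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (m.n_states,):
        raise GraphError(
            f"stationary vector has length {pi.shape}, expected {m.n_states}"
        )
    flow_in = pi @ m.T  # mass flowing into each target state (j, k)
    n = m.base.N
    rows = np.fromiter((s[0] for s in m.states), dtype=np.int64, count=m.n_states)
    cols = np.fromiter((s[1] for s in m.states), dtype=np.int64, count=m.n_states)
    F = sp.coo_array((flow_in, (rows, cols)), shape=(n, n)).tocsr()
    return DirectedGraph(list(m.base.node_ids), F)
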