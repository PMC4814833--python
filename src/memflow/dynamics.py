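"""Continuous-time random-walk dynamics on node and memory state spaces.

The walk is governed by the Kolmogorov forward equation for row vectors,
``dp/dt = p L`` with rate matrix ``L = D^{-1} A - I`` (out-degree
normalisation), so that ``p(t) = p(0) e^{tL}`` and ``(e^{tL})_{ij}`` is the
probability of reaching j from i in Markov time t.  On an undirected base
the stationary distribution is the degree-proportional ``pi_j = k_j / 2M``;
on a general directed (strongly connected) state space it is the dominant
left eigenvector of the transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .graph_core import DirectedGraph, GraphError, MemoryNetwork

__all__ = [
    "Propagator",
    "normalized_laplacian",
    "propagator",
    "stationary_distribution",
    "ensure_ergodic",
    "transition_matrix",
]

#: below this many states the matrix exponential is computed densely
_DENSE_LIMIT = 2000


def transition_matrix(obj: DirectedGraph | MemoryNetwork) -> sp.csr_array:
    """Row-stochastic one-step transition matrix of a graph or memory net."""
    if isinstance(obj, MemoryNetwork):
        if obj.T is None:
            raise GraphError("memory network has no transition matrix set")
        return obj.T
    A = sp.csr_array(obj.A, dtype=float)
    s = np.asarray(A.sum(axis=1)).ravel()
    if np.any(s <= 0):
        j = int(np.flatnonzero(s <= 0)[0])
        raise GraphError(
            f"node {obj.node_ids[j]} has no outgoing weight; "
            "run ensure_ergodic first"
        )
    return sp.csr_array(sp.diags_array(1.0 / s) @ A)


def normalized_laplacian(obj: DirectedGraph | MemoryNetwork) -> np.ndarray | sp.csr_array:
    """Rate matrix L = T - I driving ``dp/dt = p L``.

    Rows sum to zero and off-diagonal entries are nonnegative.  Raises if
    any state is dangling (zero out-weight).
    """
    T = transition_matrix(obj)
    n = T.shape[0]
    return sp.csr_array(T - sp.eye_array(n, format="csr"))


@dataclass
class Propagator:
    """The row-stochastic kernel ``e^{tL}`` at Markov time t."""

    t: float
    matrix: np.ndarray

    def __post_init__(self) -> None:
        rs = self.matrix.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise GraphError("propagator rows do not sum to one")


def propagator(L: np.ndarray | sp.sparray, t: float) -> Propagator:
    """Matrix exponential ``e^{tL}`` of the rate matrix at time t >= 0.

    Dense below 2000 states; uses the sparse matrix-exponential action
    column-block evaluation above.
    """
    if t < 0:
        raise GraphError(f"Markov time must be nonnegative, got {t}")
    n = L.shape[0]
    if sp.issparse(L) and n <= _DENSE_LIMIT:
        L = L.toarray()
    if sp.issparse(L):
        P = spla.expm_multiply(sp.csc_array(t * L).T, np.eye(n)).T
    else:
        P = scipy.linalg.expm(t * np.asarray(L, dtype=float))
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return Propagator(t=t, matrix=P)


def _strong_components(T: sp.csr_array) -> tuple[int, np.ndarray]:
    return csgraph.connected_components(T, directed=True, connection="strong")


def stationary_distribution(obj: DirectedGraph | MemoryNetwork) -> np.ndarray:
    """Stationary distribution pi with ``pi T = pi``, normalised to one.

    Requires a strongly connected state space.  Matches the closed forms
    ``pi_j = k_j / 2M`` (undirected graph) and ``pi_alpha = w_alpha / W``
    (first-order lift) to within numerical round-off.
    """
    T = transition_matrix(obj)
    n = T.shape[0]
    ncomp, labels = _strong_components(T)
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise GraphError(
            f"state space is not strongly connected: {ncomp} SCCs with sizes "
            f"{sorted(sizes.tolist(), reverse=True)[:5]}...; run ensure_ergodic"
        )
    if n == 1:
        return np.ones(1)
    if n <= _DENSE_LIMIT:
        w, V = scipy.linalg.eig(T.toarray().T)
        k = int(np.argmax(w.real))
        pi = V[:, k].real
    else:
        w, V = spla.eigs(sp.csr_matrix(T).T, k=1, which="LR")
        pi = V[:, 0].real
    pi = np.abs(pi)
    pi /= pi.sum()
    # one power-iteration polish: removes eigensolver round-off
    for _ in range(2):
        pi = pi @ T
        pi /= pi.sum()
    return pi


def ensure_ergodic(
    obj: DirectedGraph | MemoryNetwork,
    strategy: str = "largest_scc",
    teleport_rate: float = 0.15,
):
    """Make the walk ergodic by SCC restriction or uniform teleportation.

    ``largest_scc`` restricts the state space to its largest strongly
    connected component and reports what was removed (a strongly connected
    input is returned unchanged).  ``teleport`` mixes the transition matrix
    with a uniform jump at rate ``teleport_rate``, which connects
    everything at the cost of distorting the dynamics.

    Returns ``(object, report)`` where the report lists removed states.
    """
    if strategy not in ("largest_scc", "teleport"):
        raise GraphError(f"unknown ergodicity strategy {strategy!r}")

    if strategy == "teleport":
        if not (0.0 < teleport_rate < 1.0):
            raise GraphError("teleport_rate must lie in (0, 1)")
        return _teleport(obj, teleport_rate), {"strategy": "teleport",
                                               "removed": [],
                                               "teleport_rate": teleport_rate}

    if isinstance(obj, MemoryNetwork):
        mat = obj.weights if obj.weights is not None else obj.G
    else:
        mat = obj.A
    ncomp, labels = _strong_components(sp.csr_array(mat))
    if ncomp == 1:
        return obj, {"strategy": "largest_scc", "removed": []}
    sizes = np.bincount(labels)
    big = int(np.argmax(sizes))
    keep = np.flatnonzero(labels == big)
    if keep.size < 2:
        raise GraphError("largest strongly connected component has < 2 states")
    if isinstance(obj, MemoryNetwork):
        removed = [obj.state_labels()[a] for a in np.flatnonzero(labels != big)]
        sub_states = [obj.states[a] for a in keep]
        W = (
            sp.csr_array(obj.weights[keep][:, keep])
            if obj.weights is not None
            else None
        )
        from .graph_core import _line_graph_structure

        m = MemoryNetwork(
            states=sub_states,
            base=obj.base,
            G=_line_graph_structure(sub_states, obj.base.N),
        )
        if W is not None:
            m.set_weights(W, kind_tag=obj.kind_tag)
        return m, {"strategy": "largest_scc", "removed": removed}
    removed = [obj.node_ids[i] for i in np.flatnonzero(labels != big)]
    A = sp.csr_array(obj.A[keep][:, keep])
    g = DirectedGraph([obj.node_ids[i] for i in keep], A, undirected=obj.undirected)
    return g, {"strategy": "largest_scc", "removed": removed}


def _teleport(obj, rate: float):
    """Mix the transition matrix with a uniform jump at the given rate."""
    if isinstance(obj, MemoryNetwork):
        W = obj.weights if obj.weights is not None else obj.G.astype(float)
        W = sp.csr_array(W).toarray()
        s = W.sum(axis=1)
        n = W.shape[0]
        T = np.full((n, n), 1.0 / n)  # dangling states teleport uniformly
        pos = s > 0
        T[pos] = W[pos] / s[pos, None]
        T = (1 - rate) * T + rate / n
        m = MemoryNetwork(states=list(obj.states), base=obj.base,
                          G=sp.csr_array(np.ones((n, n))),
                          kind_tag=obj.kind_tag)
        m.set_weights(sp.csr_array(T), kind_tag=obj.kind_tag)
        return m
    A = sp.csr_array(obj.A, dtype=float).toarray()
    s = A.sum(axis=1)
    n = A.shape[0]
    T = np.zeros((n, n))
    pos = s > 0
    T[pos] = A[pos] / s[pos, None]
    T[~pos] = 1.0 / n
    T = (1 - rate) * T + rate / n
    return DirectedGraph(list(obj.node_ids), sp.csr_array(T))
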