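"""Parametric second-order transition model (return/triangular/exploratory).

Every admissible edge-to-edge move (i->j) -> (j->k) falls into one of
three classes: a *return* step (k = i), a *triangular* step (k != i but k
is a neighbour of i, closing a triangle), or an *exploratory* step (k
outside i's neighbourhood).  Weighting the classes with strictly positive
parameters r2, r3 and r_gt3 and row-normalising

    A_hat = r2 * G_ret + r3 * G_tri + r_gt3 * G_exp

yields a one-parameter-family of second-order walks: equal parameters
reduce to the first-order walk, r2 -> 0 approaches the non-backtracking
walk, and large r2 produces strongly backtracking dynamics.  The
parameters can be fitted to pathway data by maximum likelihood over the
observed step-type choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .graph_core import (
    DirectedGraph,
    GraphError,
    MemoryNetwork,
    PathwaySet,
    build_memory_state_space,
)

__all__ = [
    "LineGraphDecomposition",
    "MemoryParameters",
    "decompose_line_graph",
    "model_transition_matrix",
    "fit_memory_parameters",
]

log = logging.getLogger(__name__)

RETURN, TRIANGULAR, EXPLORATORY = 0, 1, 2


@dataclass
class MemoryParameters:
    """Strictly positive step-type weights (r2, r3, r_gt3).

    Only the ratios matter: row normalisation cancels a common scale, so
    fits pin r_gt3 = 1.
    """

    r2: float
    r3: float
    r_gt3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.r2, self.r3, self.r_gt3) <= 0:
            raise GraphError(
                "memory parameters must be strictly positive (ergodicity); "
                f"got r2={self.r2}, r3={self.r3}, r_gt3={self.r_gt3}"
            )


@dataclass
class LineGraphDecomposition:
    """Disjoint split of the line-graph structure into step-type supports."""

    m: MemoryNetwork
    G_ret: sp.csr_array
    G_tri: sp.csr_array
    G_exp: sp.csr_array

    def type_counts(self) -> np.ndarray:
        """Per-state availability (n_ret, n_tri, n_exp) of each step type."""
        return np.column_stack(
            [
                np.asarray(self.G_ret.sum(axis=1)).ravel(),
                np.asarray(self.G_tri.sum(axis=1)).ravel(),
                np.asarray(self.G_exp.sum(axis=1)).ravel(),
            ]
        )


def decompose_line_graph(
    g: DirectedGraph, strict_directed: bool = False
) -> LineGraphDecomposition:
    """Classify every admissible memory transition by step type.

    ``strict_directed=True`` calls k a neighbour of i only when the edge
    i->k exists; the default accepts either direction (undirected sense).
    """
    m = build_memory_state_space(g)
    n = m.n_states
    coo = m.G.tocoo()
    src = np.fromiter((s[0] for s in m.states), dtype=np.int64, count=n)
    tgt = np.fromiter((s[1] for s in m.states), dtype=np.int64, count=n)
    i = src[coo.row]  # where the walker came from
    k = tgt[coo.col]  # where it is heading
    adj = (g.A > 0).toarray()
    if not strict_directed:
        adj = adj | adj.T
    is_ret = k == i
    is_tri = ~is_ret & adj[i, k]
    is_exp = ~is_ret & ~is_tri

    def pick(mask: np.ndarray) -> sp.csr_array:
        return sp.coo_array(
            (np.ones(int(mask.sum()), dtype=np.int8),
             (coo.row[mask], coo.col[mask])),
            shape=(n, n),
        ).tocsr()

    return LineGraphDecomposition(
        m=m, G_ret=pick(is_ret), G_tri=pick(is_tri), G_exp=pick(is_exp)
    )


def model_transition_matrix(
    d: LineGraphDecomposition, p: MemoryParameters
) -> MemoryNetwork:
    """Second-order transition matrix of the parametric memory model.

    Row-normalises ``r2*G_ret + r3*G_tri + r_gt3*G_exp``; the result is
    ergodic whenever the base walk is, for any strictly positive
    parameters.
    """
    A_hat = (
        p.r2 * d.G_ret.astype(float)
        + p.r3 * d.G_tri.astype(float)
        + p.r_gt3 * d.G_exp.astype(float)
    )
    m = MemoryNetwork(states=list(d.m.states), base=d.m.base, G=d.m.G.copy())
    m.set_weights(sp.csr_array(A_hat), kind_tag="M2_model")
    return m


def _classify_transitions(
    paths: PathwaySet, g: DirectedGraph, d: LineGraphDecomposition
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of observed step types and of transitions out of each state."""
    ret = d.G_ret.tocoo()
    tri = d.G_tri.tocoo()
    type_of = {}
    for mat, tcode in ((ret, RETURN), (tri, TRIANGULAR)):
        for a, b in zip(mat.row.tolist(), mat.col.tolist()):
            type_of[(a, b)] = tcode
    sindex = d.m.state_index
    type_counts = np.zeros(3, dtype=np.int64)
    per_state = np.zeros(d.m.n_states, dtype=np.int64)
    for seq, mult in paths.paths:
        idx = [g.index_of(v) for v in seq]
        for u, v, w in zip(idx[:-2], idx[1:-1], idx[2:]):
            a = sindex.get((u, v))
            b = sindex.get((v, w))
            if a is None or b is None:
                raise GraphError(
                    f"pathway transition {seq} leaves the base graph"
                )
            type_counts[type_of.get((a, b), EXPLORATORY)] += mult
            per_state[a] += mult
    return type_counts, per_state


def fit_memory_parameters(
    paths: PathwaySet,
    g: DirectedGraph,
    strict_directed: bool = False,
) -> tuple[MemoryParameters, float]:
    """Maximum-likelihood fit of (r2, r3) with r_gt3 fixed to 1.

    Each observed transition out of state alpha chooses a specific
    successor with probability ``r_type / (n2 r2 + n3 r3 + ne)`` where
    (n2, n3, ne) count alpha's available successors of each type.  The
    log-likelihood is concave in (log r2, log r3); the optimiser is run
    from several starts.  Returns the fitted parameters and the achieved
    log-likelihood (successor-type part only, up to the constant choice
    of a specific successor within a type).
    """
    d = decompose_line_graph(g, strict_directed=strict_directed)
    counts, per_state = _classify_transitions(paths, g, d)
    if np.count_nonzero(counts) < 2:
        raise GraphError(
            "only one step type observed: the ratio is unidentified; "
            "consider reporting a bound instead of an estimate"
        )
    avail = d.type_counts().astype(float)
    # group states by availability profile for a compact likelihood
    seen = per_state > 0
    profiles, inv = np.unique(avail[seen], axis=0, return_inverse=True)
    mass = np.bincount(inv, weights=per_state[seen].astype(float))

    n2, n3, ne = counts.astype(float)

    def nll(x: np.ndarray) -> float:
        r2, r3 = np.exp(x)
        denom = profiles[:, 0] * r2 + profiles[:, 1] * r3 + profiles[:, 2]
        return -(n2 * x[0] + n3 * x[1] - float(mass @ np.log(denom)))

    best = None
    for x0 in ([0.0, 0.0], [1.0, -1.0], [-1.0, 1.0], [2.0, 2.0], [-2.0, -2.0]):
        res = scipy.optimize.minimize(nll, np.asarray(x0), method="Nelder-Mead",
                                      options={"xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    r2, r3 = np.exp(best.x)
    log.info("fitted memory parameters r2=%.4f r3=%.4f (ll=%.2f)",
             r2, r3, -best.fun)
    return MemoryParameters(float(r2), float(r3), 1.0), float(-best.fun)
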