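"""Partition comparison metrics and overlapping-node covers.

Clustering a memory network partitions the *directed edges* of the base
graph.  Projecting an edge partition back onto nodes gives a soft cover:
each node is described by the fractions of its incident edges carried by
each community, and the Shannon entropy of those fractions (the
participation entropy) quantifies how strongly the node overlaps between
communities.  Partitions are compared with the variation of information
(a metric, optionally normalised by log2 of the number of states) and
with normalised mutual information.  Logarithms are base 2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph_core import DirectedGraph, GraphError, MemoryNetwork
from .stability import Partition

__all__ = [
    "Cover",
    "edge_partition_to_cover",
    "participation_entropy",
    "variation_of_information",
    "normalized_mutual_information",
]


@dataclass
class Cover:
    """Soft node-to-community membership fractions p_i(c)."""

    fractions: dict  # node label -> {community label: fraction}

    def __post_init__(self) -> None:
        for node, fr in self.fractions.items():
            tot = sum(fr.values())
            if abs(tot - 1.0) > 1e-9:
                raise GraphError(f"fractions of node {node!r} sum to {tot}")
            if any(p < 0 for p in fr.values()):
                raise GraphError(f"negative fraction at node {node!r}")

    def entropy(self, node) -> float:
        return participation_entropy(self, node)

    def entropies(self) -> dict:
        return {v: participation_entropy(self, v) for v in self.fractions}


def edge_partition_to_cover(
    g: DirectedGraph,
    edge_partition: Partition,
    m: MemoryNetwork,
    weighted: bool = False,
) -> Cover:
    """Project a memory-state (edge) partition to node membership fractions.

    ``p_i(c)`` is the fraction of memory states incident to node i (as
    source or target; both directions of an undirected edge count) whose
    community label is c.  With ``weighted=True`` states are counted with
    their base-edge weight instead.
    """
    if edge_partition.n != m.n_states:
        raise GraphError(
            f"edge partition covers {edge_partition.n} states, memory "
            f"network has {m.n_states}"
        )
    w = m.state_weight() if weighted else np.ones(m.n_states)
    frac: dict = {v: {} for v in g.node_ids}
    for a, (i, j) in enumerate(m.states):
        c = int(edge_partition.labels[a])
        for v in {g.node_ids[i], g.node_ids[j]}:
            frac[v][c] = frac[v].get(c, 0.0) + w[a]
    out = {}
    for v, fr in frac.items():
        tot = sum(fr.values())
        if tot > 0:
            out[v] = {c: x / tot for c, x in fr.items()}
    return Cover(out)


def participation_entropy(cover: Cover, node) -> float:
    """S_i = -sum_c p_i(c) log2 p_i(c); zero iff a single community."""
    if node not in cover.fractions:
        raise GraphError(f"node {node!r} not in cover")
    p = np.asarray([x for x in cover.fractions[node].values() if x > 0])
    return float(-(p * np.log2(p)).sum())


def _contingency(p1: Partition, p2: Partition) -> np.ndarray:
    if p1.n != p2.n:
        raise GraphError(
            f"partitions cover different state sets ({p1.n} vs {p2.n})"
        )
    k1, k2 = p1.n_communities, p2.n_communities
    C = sp.coo_array(
        (np.ones(p1.n), (p1.labels, p2.labels)), shape=(k1, k2)
    ).toarray()
    return C


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def variation_of_information(
    p1: Partition, p2: Partition, normalize: bool = False
) -> float:
    """VI(p1, p2) = H(p1|p2) + H(p2|p1), in bits.

    A metric on partitions; zero iff the partitions agree up to
    relabelling.  The normalised version divides by the joint entropy
    H(p1, p2) (the normalised information distance), which bounds it to
    [0, 1], is still a metric, and equals 1 exactly when the two
    partitions share no information — e.g. the all-in-one partition
    scores 1 against any non-trivial partition, so trivial clusterings
    are maximally distant rather than spuriously close.  Two identical
    all-in-one partitions give 0.
    """
    C = _contingency(p1, p2) / p1.n
    h1 = _entropy(C.sum(axis=1))
    h2 = _entropy(C.sum(axis=0))
    h12 = _entropy(C.ravel())
    vi = max(2.0 * h12 - h1 - h2, 0.0)
    if normalize:
        vi = vi / h12 if h12 > 0 else 0.0
    return float(vi)


def normalized_mutual_information(p1: Partition, p2: Partition) -> float:
    """NMI with arithmetic-mean normalisation, in [0, 1].

    Returns 0 by convention when either partition has zero entropy (e.g.
    the all-in-one partition), 1 for identical partitions.
    """
    C = _contingency(p1, p2) / p1.n
    h1 = _entropy(C.sum(axis=1))
    h2 = _entropy(C.sum(axis=0))
    if h1 <= 0 or h2 <= 0:
        return 0.0
    i12 = h1 + h2 - _entropy(C.ravel())
    return float(max(min(i12 / (0.5 * (h1 + h2)), 1.0), 0.0))
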