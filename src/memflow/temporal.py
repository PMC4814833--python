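"""Time-stamped contact networks and the pathway-generating walker.

Event data ("at step t an edge between i and j was active") carry no
pathway statistics by themselves.  They are turned into second-order
transition counts by simulating random walkers over the event sequence:
a walker waits on its node until an incident edge is active, then leaves
with probability 1 - p_s (choosing among the active incident edges
proportionally to weight) or stays with probability p_s.  The recorded
node sequences respect the temporal ordering of the events, so the
resulting M2 network captures temporal correlations between edge
activations that the static aggregate destroys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph_core import (
    DirectedGraph,
    GraphError,
    MemoryNetwork,
    PathwaySet,
    build_m2_from_pathways,
)

__all__ = [
    "TemporalNetwork",
    "WalkerConfig",
    "aggregate_static",
    "simulate_pathways",
    "build_temporal_m2",
]

log = logging.getLogger(__name__)


@dataclass
class TemporalNetwork:
    """Ordered event list (t, source, target, weight) over steps 1..T.

    ``directed=False`` (the default for contact data) makes every event
    traversable in both directions.
    """

    node_ids: list
    t: np.ndarray          # integer step index in [1, T], sorted
    src: np.ndarray        # internal node indices
    dst: np.ndarray
    w: np.ndarray
    T: int
    directed: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.src = np.asarray(self.src, dtype=np.int64)
        self.dst = np.asarray(self.dst, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float)
        if self.t.size == 0:
            raise GraphError("temporal network has no events")
        if self.t.min() < 1 or self.t.max() > self.T:
            raise GraphError("event timestamps must lie in [1, T]")
        if np.any(np.diff(self.t) < 0):
            order = np.argsort(self.t, kind="stable")
            self.t, self.src, self.dst, self.w = (
                a[order] for a in (self.t, self.src, self.dst, self.w)
            )
        if self.w.min() <= 0:
            raise GraphError("event weights must be positive")

    @property
    def n_events(self) -> int:
        return int(self.t.size)

    @classmethod
    def from_events(
        cls,
        events,
        directed: bool = False,
        node_ids=None,
        reindex_times: bool = False,
    ) -> "TemporalNetwork":
        """Build from (t, u, v[, w]) tuples; optionally rank-transform raw
        timestamps to contiguous steps 1..T."""
        events = list(events)
        if not events:
            raise GraphError("temporal network has no events")
        order: dict = {}
        if node_ids is not None:
            for v in node_ids:
                order.setdefault(v, len(order))
        ts, ss, ds, ws = [], [], [], []
        for e in events:
            t, u, v = e[0], e[1], e[2]
            w = float(e[3]) if len(e) > 3 else 1.0
            for x in (u, v):
                if x not in order:
                    order[x] = len(order)
            ts.append(int(t))
            ss.append(order[u])
            ds.append(order[v])
            ws.append(w)
        ts = np.asarray(ts)
        if reindex_times:
            _, ts = np.unique(ts, return_inverse=True)
            ts = ts + 1
        elif ts.min() < 1:
            ts = ts - ts.min() + 1
        return cls(
            node_ids=list(order),
            t=ts,
            src=np.asarray(ss),
            dst=np.asarray(ds),
            w=np.asarray(ws),
            T=int(np.max(ts)),
            directed=directed,
        )


@dataclass
class WalkerConfig:
    """Simulation settings for the pathway-generating walker.

    ``p_s`` is the probability of declining an available move (0 = always
    take the first available edge); ``n_epochs`` repeats the full event
    sequence with fresh walker starts to accumulate transition counts.
    """

    p_s: float = 0.05
    n_walkers: int = 100
    n_epochs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_s <= 1.0):
            raise GraphError(f"stay probability must be in [0,1], got {self.p_s}")
        if self.n_walkers < 1 or self.n_epochs < 1:
            raise GraphError("n_walkers and n_epochs must be positive")


def aggregate_static(tn: TemporalNetwork) -> DirectedGraph:
    """Time-aggregated network: A_static = sum_t A_t."""
    n = len(tn.node_ids)
    rows, cols, data = tn.src, tn.dst, tn.w
    if not tn.directed:
        rows = np.concatenate([tn.src, tn.dst])
        cols = np.concatenate([tn.dst, tn.src])
        data = np.concatenate([tn.w, tn.w])
    A = sp.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()
    A.sum_duplicates()
    return DirectedGraph(list(tn.node_ids), A, undirected=not tn.directed)


def _step_adjacency(tn: TemporalNetwork):
    """Per-timestep adjacency ``src -> (targets, cumulative weights)``.

    Identical snapshots (frequent when a few activity patterns recur)
    share a single cached dictionary.
    """
    bounds = np.searchsorted(tn.t, np.arange(1, tn.T + 2))
    cache: dict = {}
    step_adj: list = []
    for t in range(tn.T):
        lo, hi = bounds[t], bounds[t + 1]
        if lo == hi:
            step_adj.append(None)
            continue
        key = (tn.src[lo:hi].tobytes(), tn.dst[lo:hi].tobytes(),
               tn.w[lo:hi].tobytes())
        adj = cache.get(key)
        if adj is None:
            adj = {}
            srcs, dsts, ws = tn.src[lo:hi], tn.dst[lo:hi], tn.w[lo:hi]
            if not tn.directed:
                srcs = np.concatenate([srcs, dsts])
                dsts = np.concatenate([dsts, tn.src[lo:hi]])
                ws = np.concatenate([ws, ws])
            for u in np.unique(srcs):
                mask = srcs == u
                tg = dsts[mask]
                cw = np.cumsum(ws[mask])
                adj[int(u)] = (tg, cw / cw[-1])
            cache[key] = adj
        step_adj.append(adj)
    return step_adj


def simulate_pathways(tn: TemporalNetwork, cfg: WalkerConfig) -> PathwaySet:
    """Simulate random-walk trajectories over the event sequence.

    Each walker starts on a uniformly random node at t = 1 and is
    propagated through the T observation steps; staying put does not
    append to the recorded node sequence, so pathways list consecutive
    *distinct* positions.  Waiting consumes timesteps but inter-event
    durations carry no extra weight.
    """
    rng = np.random.default_rng(cfg.seed)
    step_adj = _step_adjacency(tn)
    n_nodes = len(tn.node_ids)
    ids = tn.node_ids
    paths: list[tuple[list, int]] = []
    for _ in range(cfg.n_epochs):
        pos = rng.integers(0, n_nodes, size=cfg.n_walkers)
        trajs: list[list] = [[ids[p]] for p in pos]
        for t in range(tn.T):
            adj = step_adj[t]
            if adj is None:
                continue
            move_draw = rng.random(cfg.n_walkers)
            pick_draw = rng.random(cfg.n_walkers)
            for wk in range(cfg.n_walkers):
                edges = adj.get(int(pos[wk]))
                if edges is None or move_draw[wk] < cfg.p_s:
                    continue
                tg, cw = edges
                nxt = int(tg[np.searchsorted(cw, pick_draw[wk], side="right")])
                if nxt == pos[wk]:
                    continue  # self-loop event: no displacement
                pos[wk] = nxt
                trajs[wk].append(ids[nxt])
        paths.extend((tr, 1) for tr in trajs if len(tr) >= 2)
    if not paths:
        log.warning(
            "no walker ever moved (p_s=%.2f): empty pathway set", cfg.p_s
        )
    return PathwaySet(paths)


def build_temporal_m2(
    tn: TemporalNetwork, cfg: WalkerConfig
) -> tuple[MemoryNetwork, dict]:
    """Simulate pathways and estimate the M2 network of a temporal graph.

    Returns the memory network together with a report on the number of
    edge-to-edge transitions collected and the coverage of the static
    edge set (states never visited end up with zero out-weight and are
    handled by downstream ergodicity preprocessing).
    """
    g = aggregate_static(tn)
    paths = simulate_pathways(tn, cfg)
    if paths.n_transitions() == 0:
        raise GraphError(
            "walkers produced no edge-to-edge transition; "
            "increase n_walkers/n_epochs or lower p_s"
        )
    m = build_m2_from_pathways(paths, g=g)
    m.kind_tag = "M2_temporal"
    dangling = m.dangling_states()
    report = {
        "n_transitions": paths.n_transitions(),
        "n_states": m.n_states,
        "n_unvisited_states": int(dangling.size),
        "edge_coverage": 1.0 - dangling.size / m.n_states,
    }
    log.info("temporal M2: %s", report)
    return m, report
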