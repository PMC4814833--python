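"""Synthetic generators with planted structure.

Three families make every pipeline testable end-to-end without external
downloads:

* a *temporal group benchmark*: a complete directed graph whose edges
  are split into g groups (each node keeps an equal number of outgoing
  edges per group); at every timestep exactly one group's edges are
  active, and the active group persists with probability p_k, otherwise
  a new group is drawn uniformly (including the current one).  Large
  p_k lets a walker linger inside one edge group, so the M2 network
  built from its trajectories carries the planted edge partition;
* two-group stochastic-block-model samples for the spectral pipeline;
* pathway sets sampled from the parametric memory model, standing in
  for trajectory corpora (e.g. itinerary data) when only an aggregated
  network is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dynamics import ensure_ergodic, stationary_distribution
from .graph_core import (
    DirectedGraph,
    GraphError,
    MemoryNetwork,
    PathwaySet,
    build_m2_from_pathways,
)
from .memory_model import (
    LineGraphDecomposition,
    MemoryParameters,
    decompose_line_graph,
    model_transition_matrix,
)
from .stability import Partition, sweep_markov_time
from .temporal import TemporalNetwork, WalkerConfig, aggregate_static, simulate_pathways

__all__ = [
    "TemporalBenchmarkConfig",
    "generate_temporal_benchmark",
    "generate_sbm_bipartition",
    "generate_model_pathways",
    "benchmark_recovery_curve",
    "planted_edge_partition",
]

log = logging.getLogger(__name__)


@dataclass
class TemporalBenchmarkConfig:
    """Settings of the planted-edge-group temporal benchmark.

    The complete directed graph on N nodes is split into g edge groups
    with (N-1)/g outgoing edges per node per group, so g must divide
    N-1.  ``p_k`` is the per-step persistence of the active group.
    """

    N: int = 10
    g: int = 3
    p_k: float = 0.5
    T: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.N - 1) % self.g:
            raise GraphError(
                f"group count {self.g} must divide N-1 = {self.N - 1}"
            )
        if not (0.0 <= self.p_k <= 1.0):
            raise GraphError("persistence p_k must lie in [0, 1]")


def generate_temporal_benchmark(
    cfg: TemporalBenchmarkConfig,
) -> tuple[TemporalNetwork, dict]:
    """Planted temporal benchmark: events plus the edge-group labels.

    Returns the temporal network (directed events, unit weight) and a
    mapping ``(u, v) -> group`` over all N(N-1) directed edges.
    """
    rng = np.random.default_rng(cfg.seed)
    per_group = (cfg.N - 1) // cfg.g
    groups: dict[tuple[int, int], int] = {}
    for i in range(cfg.N):
        others = np.asarray([j for j in range(cfg.N) if j != i])
        rng.shuffle(others)
        for pos, j in enumerate(others):
            groups[(i, int(j))] = pos // per_group
    edges_of = [
        np.asarray([e for e, c in groups.items() if c == k], dtype=np.int64)
        for k in range(cfg.g)
    ]
    # active-group sequence: keep with p_k, else uniform (incl. current)
    active = np.empty(cfg.T, dtype=np.int64)
    active[0] = rng.integers(cfg.g)
    keep = rng.random(cfg.T - 1) < cfg.p_k
    fresh = rng.integers(0, cfg.g, size=cfg.T - 1)
    for t in range(1, cfg.T):
        active[t] = active[t - 1] if keep[t - 1] else fresh[t - 1]
    counts = np.asarray([edges_of[k].shape[0] for k in active])
    ts = np.repeat(np.arange(1, cfg.T + 1), counts)
    ee = np.concatenate([edges_of[k] for k in active])
    tn = TemporalNetwork(
        node_ids=list(range(cfg.N)),
        t=ts,
        src=ee[:, 0],
        dst=ee[:, 1],
        w=np.ones(ee.shape[0]),
        T=cfg.T,
        directed=True,
    )
    return tn, groups


def planted_edge_partition(m: MemoryNetwork, groups: dict) -> Partition:
    """Align a planted (u, v) -> group mapping with a memory state space."""
    ids = m.base.node_ids
    return Partition(
        np.asarray([groups[(ids[i], ids[j])] for i, j in m.states])
    )


def generate_sbm_bipartition(cfg) -> tuple[DirectedGraph, np.ndarray]:
    """Sample a two-equal-group SBM and its planted +/-1 labels.

    Each within-group pair is linked with probability c_in/N and each
    across-group pair with c_out/N; the sample is undirected without
    self-loops.  ``cfg`` is a :class:`memflow.spectral.SBMConfig`.
    """
    rng = np.random.default_rng(cfg.seed)
    N, half = cfg.N, cfg.N // 2
    p_in, p_out = cfg.c_in / N, cfg.c_out / N
    if p_in > 1.0 or p_out > 1.0:
        raise GraphError(
            f"SBM parameters imply edge probabilities > 1 "
            f"(p_in={p_in:.3f}, p_out={p_out:.3f})"
        )
    iu, ju = np.triu_indices(half, k=1)
    rows, cols = [], []
    for offset in (0, half):  # the two within-group blocks
        mask = rng.random(iu.shape[0]) < p_in
        rows.append(iu[mask] + offset)
        cols.append(ju[mask] + offset)
    between = rng.random((half, half)) < p_out
    bi, bj = np.nonzero(between)
    rows.append(bi)
    cols.append(bj + half)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.ones(rows.shape[0])
    A = sp.coo_array(
        (np.concatenate([data, data]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(N, N),
    ).tocsr()
    labels = np.concatenate([np.ones(half), -np.ones(half)]).astype(np.int64)
    return DirectedGraph(list(range(N)), A, undirected=True), labels


def generate_model_pathways(
    g: DirectedGraph,
    p: MemoryParameters,
    n_paths: int = 1000,
    path_length: int = 100,
    seed: int = 0,
    d: LineGraphDecomposition | None = None,
) -> PathwaySet:
    """Sample trajectories from the parametric memory model.

    Each path starts on a memory state drawn from the model chain's
    stationary distribution and follows T^model for ``path_length - 2``
    further steps, then is written out as a node sequence.
    """
    rng = np.random.default_rng(seed)
    if d is None:
        d = decompose_line_graph(g)
    m = model_transition_matrix(d, p)
    pi = stationary_distribution(m)
    T = m.T.toarray()
    n = m.n_states
    cur = rng.choice(n, size=n_paths, p=pi)
    seqs = np.empty((n_paths, max(path_length - 1, 1)), dtype=np.int64)
    seqs[:, 0] = cur
    for step in range(1, path_length - 1):
        nxt = np.empty(n_paths, dtype=np.int64)
        for a in np.unique(cur):
            mask = cur == a
            nxt[mask] = rng.choice(n, size=int(mask.sum()), p=T[a])
        cur = nxt
        seqs[:, step] = cur
    ids = g.node_ids
    paths = []
    for row in seqs:
        nodes = [ids[m.states[row[0]][0]]] + [ids[m.states[a][1]] for a in row]
        paths.append((nodes, 1))
    return PathwaySet(paths)


def benchmark_recovery_curve(
    p_k_grid,
    N: int = 10,
    g: int = 3,
    T: int = 5000,
    n_walkers: int = 50,
    n_realisations: int = 5,
    t_grid=None,
    n_runs: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted-partition recovery of the temporal benchmark vs p_k.

    For each persistence value and realisation: generate the benchmark,
    simulate walkers with p_s = 0 (a nonzero stay probability is
    equivalent to lowering p_k on this benchmark), build the M2 network,
    sweep linearised Markov stability over a log-grid of times around
    t = 1, and record the minimum normalised VI against the planted
    edge partition together with the time at which it is attained.

    Returns a tidy frame with one row per (p_k, realisation).
    """
    from .partition_metrics import variation_of_information

    if t_grid is None:
        t_grid = np.logspace(-0.5, 0.5, 11)
    rows = []
    rng = np.random.default_rng(seed)
    for p_k in p_k_grid:
        for r in range(n_realisations):
            s = int(rng.integers(2**31 - 1))
            cfg = TemporalBenchmarkConfig(N=N, g=g, p_k=float(p_k), T=T, seed=s)
            tn, groups = generate_temporal_benchmark(cfg)
            gstat = aggregate_static(tn)
            paths = simulate_pathways(
                tn, WalkerConfig(p_s=0.0, n_walkers=n_walkers, n_epochs=1,
                                 seed=s + 1)
            )
            m = build_m2_from_pathways(paths, g=gstat)
            m, rep = ensure_ergodic(m, strategy="largest_scc")
            planted = planted_edge_partition(m, groups)
            curve = sweep_markov_time(
                m, t_grid, n_runs=n_runs, seed=s + 2, linearized=True
            )
            vis = np.asarray([
                variation_of_information(e.partition, planted, normalize=True)
                for e in curve.entries
            ])
            k = int(np.argmin(vis))
            attained = np.flatnonzero(vis <= vis[k] + 1e-12)
            rows.append({
                "p_k": float(p_k),
                "realisation": r,
                "min_vi": float(vis[k]),
                "t_opt": curve.entries[k].t,                  # first optimum
                "t_opt_hi": curve.entries[attained[-1]].t,    # last optimum
                "n_communities_opt": curve.entries[k].n_communities,
                "n_removed_states": len(rep["removed"]),
            })
            log.info("benchmark p_k=%.2f real=%d min_vi=%.3f t_opt=%.2f",
                     p_k, r, vis[k], curve.entries[k].t)
    return pd.DataFrame(rows)
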