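# memflow

Flow-based community detection driven by **second-order (memory) Markov
dynamics** on networks.

First-order random walks forget where they came from, but real flows —
passengers between airports, face-to-face contacts over a school day,
information cascades — do not: where a walker goes next depends on where it
arrived from. `memflow` models such flows as a second-order Markov process,
which is a *first-order* walk on a **memory network** (the "M2" network):
the state space of ordered node pairs, i.e. the directed edges of the base
graph, wired as a directed line graph. Clustering this state space yields a
partition of the *edges* of the original network, which reads back onto the
nodes as an *overlapping* community structure.

The package is aimed at network scientists and systems biologists who have
one of the following and want flow-respecting communities out of it:

* a weighted (di)graph — analysed through the first-order lift `M1ext`;
* pathway/trajectory data (sequences of nodes) — turned into an empirical
  M2 transition matrix by trigram counting;
* time-stamped contact events ("`t i j w`", SocioPatterns style) — turned
  into pathways by a temporal random-walk simulator, then into an M2 network;
* only an aggregated graph plus qualitative knowledge about memory — covered
  by a 3-parameter transition model that can also be fitted to pathway data.

## The quality function

A continuous-time walk `dp/dt = p L` with `L = D_out^{-1} A − I` defines, for
any partition into communities `C` at Markov time `t`, the **Markov
stability**

```
R(t) = Σ_C Σ_{i,j∈C} [ π_i (e^{tL})_{ij} − π_i π_j ]
```

— the excess probability that a walker starting in a community at
stationarity is found in the same community a time `t` later. Writing
`Y_ij(t) = π_i (e^{tL})_{ij}`, `R(t)` is exactly the Newman–Girvan modularity
of the flow network `Y`, so stability is optimised here with a (generalised,
seeded, best-of-n) Louvain heuristic on `(Y + Yᵀ)/2 − ππᵀ`. The linearised
variant replaces `e^{tL}` by its first-order Taylor expansion and reduces, on
undirected graphs at `t = 1`, to plain modularity. Small `t` resolves fine
structure, large `t` coarse structure; partitions that persist over a range
of `t` (plateaux with zero between-run variation of information) are the
robust ones. Running the same machinery on a memory network makes the
communities respect second-order flow constraints.

Two further ingredients connect the framework outward:

* a **step-type decomposition** of the line graph into return, triangular
  and exploratory moves, weighted `r2 : r3 : r>3` — equal weights recover the
  first-order walk, `r2 → 0` the non-backtracking walk; the weights are
  fittable from pathway data by maximum likelihood;
* the **non-backtracking matrix** `B` and its transition version `T^B`,
  whose second eigenvector bipartitions sparse stochastic-block-model graphs
  down to the detectability limit `c* = ((1 + ε)/(1 − ε))²` for mixing ratio
  `ε = c_out/c_in` (`c* ≈ 3.45` at `ε = 0.3`).

## Worked example: communities in a temporal benchmark

The built-in benchmark plants 3 edge groups in a complete directed graph on
10 nodes (3 outgoing edges per node per group); at each of `T = 5000` steps
one group's edges are active, and the active group persists with probability
`p_k`. Walkers (stay probability 0) turn the event stream into pathways, the
pathways into an M2 network, and a sweep of linearised stability recovers
the planted edge partition:

```python
import numpy as np
from memflow import (TemporalBenchmarkConfig, generate_temporal_benchmark,
                     WalkerConfig, simulate_pathways, aggregate_static,
                     build_m2_from_pathways, sweep_markov_time,
                     planted_edge_partition, variation_of_information)

cfg = TemporalBenchmarkConfig(N=10, g=3, p_k=0.8, T=5000, seed=0)
tn, groups = generate_temporal_benchmark(cfg)
paths = simulate_pathways(tn, WalkerConfig(p_s=0.0, n_walkers=50, seed=1))
m = build_m2_from_pathways(paths, g=aggregate_static(tn))
curve = sweep_markov_time(m, np.logspace(-0.5, 0.5, 11), n_runs=5,
                          seed=2, linearized=True)
planted = planted_edge_partition(m, groups)
for e in curve.entries:
    vi = variation_of_information(e.partition, planted, normalize=True)
    print(f"t={e.t:5.2f}  communities={e.n_communities:3d}  "
          f"R={e.stability:6.3f}  VI_planted={vi:.3f}")
```

```
t= 0.32  communities= 17  R= 0.757  VI_planted=0.609
t= 0.40  communities= 14  R= 0.712  VI_planted=0.579
t= 0.50  communities= 11  R= 0.661  VI_planted=0.533
t= 0.63  communities=  7  R= 0.609  VI_planted=0.418
t= 0.79  communities=  5  R= 0.559  VI_planted=0.283
t= 1.00  communities=  3  R= 0.527  VI_planted=0.000
t= 1.26  communities=  3  R= 0.491  VI_planted=0.000
t= 1.58  communities=  3  R= 0.445  VI_planted=0.000
t= 2.00  communities=  3  R= 0.387  VI_planted=0.085
t= 2.51  communities=  3  R= 0.317  VI_planted=0.000
t= 3.16  communities=  3  R= 0.226  VI_planted=0.085
```

Reading the table: at short Markov times the optimiser shatters the 90
memory states into many small communities (high VI against the planted
3-group partition); from `t = 1` onward it locks onto exactly the 3 planted
edge groups (normalised VI 0) and stays there — the plateau that marks a
robust partition. At low persistence (`p_k ≲ 0.3`) no Markov time recovers
the groups, because a walker hops between edge types too quickly for memory
to matter.

## Command line

```bash
memflow cluster --input edges.tsv --pipeline m1ext \
    --t-grid log:-1:1:20 --runs 20 --seed 7 --out results/
memflow temporal-m2 --events contacts.tsv --ps 0.05 --walkers 200 --out results/
memflow spectral --operator tb --sbm N=2000,c=8,ratio=0.3 --seed 2
memflow benchmark --pk 0.0:1.0:0.1 --out benchmark.csv
```

For instance the spectral command prints:

```
detectability limit c* = 3.449
groups of sizes [1010, 985], NMI vs planted = 0.463
```

`temporal-m2` with `--ps 0.05` is the pipeline to point at a SocioPatterns
contact file (`--reindex-times` maps raw 20-second epochs to contiguous
steps) when you have such data; it writes the stability curve, the best edge
partition and a run manifest.

## Layout

| module | contents |
| --- | --- |
| `graph_core` | `DirectedGraph`, memory state spaces, first-order lift, trigram M2 estimation, node projection |
| `dynamics` | rate matrices, matrix-exponential propagators, stationary distributions, ergodicity handling (SCC / teleport) |
| `stability` | Markov stability (full + linearised), flow-modularity rewriting, generalised Louvain, Markov-time sweeps |
| `memory_model` | return/triangular/exploratory decomposition, parametric `T^model`, maximum-likelihood fitting |
| `temporal` | contact-event containers, temporal walker, M2-from-events |
| `partition_metrics` | edge-partition → node cover, participation entropy, VI, NMI |
| `spectral` | non-backtracking `B` and `T^B`, spectral bipartition, detectability threshold |
| `synthetic` | planted temporal benchmark, SBM sampler, model-pathway generator, recovery curves |
| `cli_io`, `cli` | file formats, result writers, the `memflow` command |
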