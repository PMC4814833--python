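# Methods

This note records the models implemented in `memflow`, the conventions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Dynamics and state spaces

All dynamics are continuous-time random walks acting on row vectors,

    dp/dt = p L,      L = D_out^{-1} A − I,

so `(e^{tL})_{ij}` is the probability of being at `j` a Markov time `t`
after starting at `i`. On a strongly connected state space the stationary
distribution `π` is the dominant left eigenvector of the transition matrix
`T = D_out^{-1} A`; on undirected graphs it has the closed form
`π_j = k_j / 2M`, and on the first-order lift (`M1ext`) it is
`π_α = w_α / W` (edge weight over total weight). Both closed forms are
verified to 1e−10 in the tests.

A second-order walk on the base graph is represented as a first-order walk
on the **memory network**: one state per directed edge (two per undirected
edge, hence `2M` states), with transitions admissible only between
`(i, j) → (j, k)` — the directed line graph. Three constructions populate
its weights:

* `lift_first_order` — transition to `(j, k)` proportional to the base
  weight `A_jk`; projects back exactly onto the first-order node walk.
* `build_m2_from_pathways` — overlapping trigram counts: a pathway of `L`
  nodes contributes `L − 2` edge-to-edge transitions, weighted by its
  multiplicity. Counts are unsmoothed by default; an optional pseudocount
  spreads uniform mass over line-graph-admissible successors only, so
  smoothing can never create inadmissible transitions. States never
  observed keep zero out-weight and are left to the ergodicity layer.
* `model_transition_matrix` — the parametric model below.

**Ergodicity.** Two strategies: restriction to the largest strongly
connected component (reported; the default, matching the practice of using
the untouched dynamics when the largest SCC dominates), or uniform
teleportation at a configurable rate (default 0.15, the usual PageRank
smoothing; the rate is a knob because no canonical value exists). Tests
check that the teleported chain's stationary distribution converges to the
untouched one as the rate goes to 0.

**Matrix exponentials** are computed densely (`scipy.linalg.expm`) below
2000 states and by the sparse action of the exponential above; propagator
rows are clipped at 0 and renormalised, and the semigroup property is
tested to 1e−8.

## Markov stability and its optimisation

    R(t) = Σ_C Σ_{i,j∈C} [ π_i (e^{tL})_{ij} − π_i π_j ]

with the identities: `R = 0` for the all-in-one partition at every `t`;
`R(0) = 1 − Σ π_i²` for singletons; `R(t) = e^{−2t}/2` on the two-node
chain. The linearised variant

    R_lin(t) = Σ_C Σ_{i,j∈C} [ (1−t) δ_ij π_i + t π_i T_ij − π_i π_j ]

anchors the Taylor expansion at `t = 0` and equals Newman–Girvan modularity
on undirected graphs at `t = 1`. For directed state spaces (every memory
network is directed) the null term uses the dominant-eigenvector `π`, which
is *not* the directed modularity of the original network. The linearised
variant is the default for memory networks: it needs no matrix exponential
and is the form used for the pathway analyses.

**Optimisation.** `R(t)` is exactly the modularity of the flow network
`Y_ij = π_i (e^{tL})_{ij}` under the null `π_i π_j`, and symmetrising
`(Y + Yᵀ)/2` changes no partition's quality, so stability is maximised by a
Louvain heuristic on the dense symmetric quality matrix
`B = (Y + Yᵀ)/2 − ππᵀ`. The implementation is in-package because the
quality matrix has an arbitrary (non-degree) null and, for `t > 1`,
negative diagonal entries, which the graph-based Louvain implementations in
common libraries do not accept. Randomness enters only through the seeded
node order; the best of `n_runs` (default 20) is returned, and a run whose
optimum does not exceed 0 (the all-in-one quality) collapses to the trivial
partition — this is the exact-stationarity limit `t → ∞`, where `Y → ππᵀ`
and no partition beats independence. Louvain is validated against
exhaustive partition search on 8-node fixtures.

**Sweeps and robustness.** Markov-time grids are logarithmic, by default
decades around `t = 1`. For each grid point the sweep records the best
partition, its stability, the community count, and the mean pairwise
normalised VI across the run optima; a plateau is ≥ 3 consecutive grid
points with constant community count and run-VI < 0.05. These two constants
operationalise the qualitative notion of a "robust plateau" and are
exposed as arguments.

## The three-parameter memory model

Every admissible move `(i→j) → (j→k)` is classified as a **return**
(`k = i`), **triangular** (`k ≠ i` and `k` adjacent to `i` — adjacency in
the undirected sense `A_ik > 0` or `A_ki > 0` by default, with a
`strict_directed` flag), or **exploratory** step. The three boolean
matrices partition the line graph exactly (tested). Weights
`Â = r2·G_ret + r3·G_tri + r>3·G_exp` with strictly positive parameters,
row-normalised, give `T^model`; equal parameters reduce to the first-order
walk, and `r2 → 0` with `r3 = r>3 = 1` converges to the non-backtracking
transition matrix `T^B` (the `r2 = 0` endpoint itself lives in the spectral
module, where ergodicity is not required; the model type enforces strict
positivity because ergodicity of the base walk is preserved only then).

**Fitting.** How to calibrate `(r2, r3, r>3)` from data is genuinely open;
the package's choice is exact maximum likelihood on the observed
step-type choices. A transition out of state `α` picks a specific
successor of type `τ` with probability `r_τ / (n2(α) r2 + n3(α) r3 + ne(α))`
where `(n2, n3, ne)(α)` count `α`'s available successors per type; the
log-likelihood is optimised over `(log r2, log r3)` with `r>3 ≡ 1`, since
row normalisation makes the model invariant to overall scale (only ratios
are identified). States are grouped by availability profile, so the
objective costs O(#profiles) per evaluation; Nelder–Mead from five starts
guards against a flat direction when one step type is rare. Degenerate
data with a single observed step type is rejected with a message rather
than returning an unbounded estimate. Recovery of `(3, 1.5)` within ±10%
from 1e5 simulated transitions is part of the acceptance tests.

## Temporal networks and the pathway simulator

Events are integer-stamped contacts on steps `1..T`, undirected by default
(traversable both ways). The static aggregate is `Σ_t A_t`. The simulator
places each walker on a uniform random node at `t = 1`; at every step with
at least one active incident edge the walker moves with probability
`1 − p_s`, choosing among active incident edges proportionally to weight,
and stays otherwise. Staying and waiting consume time but emit nothing:
recorded pathways are sequences of consecutive *distinct* positions, so the
M2 network counts only genuine edge-to-edge moves (the memory state space
has no self-memory states). Inter-event durations are not weighted.
Defaults: `p_s = 0.05` (the value used for the school-contact style of
analysis; on the planted benchmark `p_s` is redundant with the persistence
parameter and is set to 0), one epoch, and walker counts chosen per
analysis; the number of epochs is a convergence knob — doubling the number
of collected transitions halves the standard error of the estimated
transition probabilities. Identical seeds give identical pathway sets.
Snapshot adjacency structures are cached by content, which makes the
benchmark (three distinct snapshots recurring over 5000 steps) cheap.

## Partition metrics

Edge partitions are projected to node covers by counting, for each node,
the incident memory states (both directions of an undirected edge, as
source or target) per community — by count by default, by weight
optionally. The participation entropy `S_i = −Σ_c p_i(c) log2 p_i(c)` is 0
for single-community nodes, 1 bit for an even two-way split. Logarithms
are base 2 throughout, making "entropy below one bit" the natural
single-community threshold.

**VI.** `VI = H(X|Y) + H(Y|X)` in bits. The *normalised* VI divides by the
joint entropy `H(X, Y)` (the normalised information distance): still a
metric, bounded in [0, 1], equal to 1 exactly for zero-information pairs.
This convention (rather than dividing by `log N`) is deliberate: the
benchmark analysis asks "how far is the recovered partition from the
planted one?", and under a `log N` normalisation the *trivial* all-in-one
partition would score a misleadingly small distance (≈ `H(planted)/log N`)
from any planted partition, placing it below reasonable thresholds and
making "recovery" appear to succeed with no information recovered. With
joint-entropy normalisation every zero-information partition — trivial or
shattered — is at distance 1. **NMI** uses arithmetic-mean normalisation
`I/((H1+H2)/2)`, with the convention 0 when either entropy vanishes; it
matches scikit-learn's implementation to 1e−10 in the tests (scikit-learn
is a cross-check there, not a dependency of the implementation).

## Spectral clustering and detectability

`B[α, β] = 1` iff `β` continues `α` and is not its reversal — identically
`G_tri + G_exp`. `T^B` is its row normalisation and requires every state to
have a non-backtracking continuation; `drop_dangling=True` restricts to the
2-core first. Bipartitioning follows the standard protocol: second
dominant left eigenvector (eigenvalues by descending real part; if it is
complex its real part is used with a warning — above the detectability
threshold it is real), per-node sum over incoming memory states, sign
gives the group, zero sums deterministically +1. Nodes outside the 2-core
are kept in the node count and assigned +1.

The SBM sampler draws within-pair edges with probability `c_in/N` and
across-pair edges with `c_out/N` (two equal groups, undirected, no
self-loops), so the average within/across degrees are `c_in/2` and
`c_out/2` and the mean degree is `c = (c_in + c_out)/2`. The detectability
condition `c_in − c_out = 2√c` then gives the closed form
`c* = ((1 + ε)/(1 − ε))²` at ratio `ε = c_out/c_in` — `c* = 3.449` at
`ε = 0.3`, diverging as `ε → 1` (equal rates are undetectable at any
degree).

Measured behaviour (recomputed by the test suite): mean NMI of the
`T^B` bipartition on `N = 2000`, `ε = 0.3` samples rises from ≈ 0 near
`c*` through ≈ 0.3 at `c = 6` to ≈ 0.5 at `c = 8`, indistinguishable from
`B` to well within 0.1, and is unchanged at `N = 10⁴`. This is the
expected *partial*-recovery regime: at `c = 8` the signal-to-threshold
ratio is only `√(c/c*) ≈ 1.5`, so a sign-based spectral rule classifies
≈ 89% of nodes correctly, which corresponds to NMI ≈ 0.5 — near-perfect
NMI (> 0.8) would require `c ≈ 16` at this mixing ratio. Claims that this
setting yields NMI > 0.8 overestimate what any second-eigenvector method
can deliver here.

## Synthetic generators: what they emulate, and what not

* **Temporal benchmark** — complete directed graph on `N = 10` nodes,
  `g = 3` edge groups, exactly `(N−1)/g = 3` outgoing edges per node per
  group (assignment: seeded per-node random allocation; any balanced
  assignment works since recovery is driven by the activity dynamics, not
  by which edges share a group). One group active per step; persistence
  `p_k`, resampling uniform *including* the current group, so the
  effective per-step persistence is `p_k + (1−p_k)/g` (verified against
  geometric run lengths). Defaults `T = 5000`, 50 walkers, 5 realisations
  per grid point; the recovery curve reports the minimum normalised VI
  over the time sweep, i.e. the best the method can do anywhere on its
  resolution axis. The benchmark emulates synchronised edge-type
  activity; it has none of the burstiness, daily rhythm or degree
  heterogeneity of real contact data, so passing it shows the pipeline
  recovers planted temporal correlation, not that it handles realistic
  contact streams.
* **SBM sampler** — two equal groups only; no degree correction. Sparse
  samples contain trees and degree-1 tendrils, which is precisely the
  regime the non-backtracking operator exists for.
* **Model pathways** — stationary starts (first edge drawn from the model
  chain's stationary distribution), then `T^model` steps; a stand-in for
  trajectory corpora such as itineraries. Real trajectory data has
  length heterogeneity and non-stationary starts that the generator does
  not emulate.

## Numerical choices and degenerate inputs

* Stationary distributions: dense eigendecomposition below 2000 states,
  ARPACK above, two power-iteration polish steps; entries are
  non-negative by construction and sum to 1.
* Louvain move tolerance 1e−15; pass cap 64 (never reached in practice);
  aggregation recurses until no merge improves the quality.
* Empty communities are impossible by construction; partition labels are
  canonicalised by first appearance, making all metrics relabelling-
  invariant.
* Dangling memory states (never-observed edges, walk sinks) raise errors
  that name the state and point to the ergodicity layer; `p_s = 1`
  (frozen walkers) yields an empty pathway set and a warning rather than
  an exception.
* Multiplicities, weights and timestamps are validated on construction;
  file readers report the offending line number.

## Known limitations

* Second order only; no variable-order or higher-order model selection.
* Louvain inherits modularity's resolution limit and optimum degeneracy;
  the time sweep mitigates but does not remove them.
* The temporal walker treats all inter-event gaps equally (no duration
  weighting) and does not model a leave probability proportional to the
  number of available contacts.
* Spectral bipartition handles exactly two planted groups; no
  Bethe-Hessian variant, no belief-propagation comparison.
* Analyses of proprietary itinerary data and of the SocioPatterns school
  stream are supported at the format/pipeline level (`memflow temporal-m2`,
  pathway files) but ship with no data; results on them are not part of
  the test suite.
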