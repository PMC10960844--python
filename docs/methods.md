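# Methods

## Objective

A partition of the vertices of a hypergraph H induces a *compression*
γ = ({C_i}, {e_λ}): the cluster sizes plus the count e_λ of edges of each
λ-type (λ_i = |A ∩ C_i|, counted with multiplicity).  The package clusters
by minimizing log Z(γ), where Z(γ) is the number of hypergraphs compatible
with γ.  Minimizing log Z is equivalent to maximizing the mutual
information between the hypergraph and a hypergraph resampled uniformly
from the compression, and to maximum-likelihood estimation in the
corresponding microcanonical stochastic blockmodel; the random-variable
formulation is never computed directly — the optimizer only ever evaluates
log Z.

Counting models:

* `simple` — Z = Π_λ C(N_λ, e_λ) with N_λ = Π_i C(|C_i|, λ_i).  Requires a
  simple input (no repeated-vertex edges, no duplicate edges); for any
  partition of a genuinely simple hypergraph the counts are automatically
  feasible (e_λ ≤ N_λ).
* `multiset` — Z = Π_λ N_λ^{e_λ} = Π_{A∈E} Π_i C(|C_i|, |A∩C_i|); parallel
  edges allowed, repeated-vertex edges not.
* `degree_corrected` — the compression carries the degree sequence.
  Degrees are treated as distinguishable stubs: stubs are assigned to
  λ-types (a(γ) = Π_i multinomial(e_i; …, λ_i e_λ, …) ways), grouped into
  packets of size λ_i and combined into edges (c(γ) ways), giving the
  closed form Z = Π_i e_i! / (Π_λ e_λ! · Π_λ Π_i (λ_i!)^{e_λ}) with
  e_i = Σ_λ λ_i e_λ.  This count permits repeated vertex inclusions and
  parallel edges, so it *approximates* the exact degree-corrected count;
  the approximation is good in the large sparse limit where such
  collisions are rare.  The value depends on the degree sequence only
  through the cluster degree sums e_i (verified by a permutation-invariance
  test).
* `graph` — the module-matrix count for simple 2-uniform inputs,
  Z = Π_{i<j} C(|C_i||C_j|, M_ij) · Π_i C(C(|C_i|,2), M_ii).  Term by term
  this is exactly the `simple` count restricted to 2-uniform edges, and the
  incremental machinery shares that code path; the standalone
  `log_z_graph` is kept as an independent formula and cross-checked
  numerically against `log_z_simple` in the tests.

All entropies are computed in natural log via `math.lgamma`; counts
overflow fixed-width integers already at a few hundred vertices, so no
big-integer arithmetic is used except inside `log_comb`, which switches
from the lgamma difference to an exact k-term sum of logs once the base
exceeds 10⁶ (beyond that the lgamma difference carries ~N·log N·ε absolute
noise).  Bits appear only in model selection (÷ log 2).

## Incremental evaluation

`EntropyState` keeps, for one assignment: the interned λ-type of every
edge, per-type counts, cluster sizes and cluster degree sums, plus
per-vertex incidence lists.  A single-vertex relabel v: a→b changes the
types of the edges incident to v and the two cluster summaries.  For the
degree-corrected model the change in log Z is a handful of
lgamma-table lookups per incident edge (the model does not involve cluster
sizes at all); type transitions (type, a, b, multiplicity) are memoized.
For the size-dependent models the summary over all realized types is
re-evaluated under old and new sizes — the realized-type set is small
(≤ C(m+k−1, k) for maximum edge size k, e.g. seven types for m = 2,
k = 3), so this stays O(deg(v) + #types).  Deltas are computed without
mutation and committed only on acceptance; the cached log Z is refreshed
from the summary every 8192 accepted moves to cap floating-point drift,
and reported optima are always recomputed from scratch.

## Annealing

Metropolis–Hastings on assignment vectors: start from i.i.d. uniform
labels over {0..m−1}, propose (vertex, label) uniformly on the n×m grid
(the current label may be re-proposed, so ~1/m of proposals are no-ops),
accept with probability min{1, exp(−β(t)·Δ log Z)}, β(t) = (t+1)·rate.
Defaults: 20 000 steps and rate 10⁻⁴, the calibrated schedule (an order of
magnitude up or down performs worse); the schedule is linear with no
restarts and resets per run, and each of the R runs in `multi_run` is an
independent chain with seed `master + run index` (run 0 therefore
reproduces a plain `anneal` call).  The best-seen assignment is tracked
and returned; ties across runs go to the lowest run index.  m is a label
budget: clusters may end up empty, and the annealer never removes labels.
Because β is applied to a natural-log entropy, switching the entropy to
bits would implicitly rescale the schedule by log 2.

## Model selection

`description_length` prices a clustering in bits as
n·log₂ m + Σ_{k=2}^{k*} C(m+k−1, k)·log₂ ℓ_k + log₂ Z(γ), with ℓ_k the
number of size-k edges.  ℓ_k ≤ 1 terms contribute zero (no smoothing; log 0
is never evaluated), size-1 edges are priced only through log Z, and the
label cost uses the full budget m even when clusters are empty.
`select_m` anneals `replicates` times per candidate m and picks the
argmin of the mean description length, breaking ties toward smaller m.
The entropy model defaults to degree-corrected and is overridable; note
that this coding scheme is known to underestimate the number of clusters
relative to generative ground truth, so tests on planted data assert
m* ≤ truth rather than equality.

## Synthetic generators

**Planted partition.**  Two communities of n vertices; exactly 5n 2-edges
and round(10n/3) 3-edges, so each vertex sees on average five 2-edges and
(for n = 200, where 10n/3 = 666.7 rounds to 667) five 3-edges.
round(p₂·5n) 2-edges are within-community (split as evenly as possible
between the two communities), the rest have one endpoint in each;
round(p₃·n₃) 3-edges are fully within (even split), the rest are 2+1 with
the majority side alternating deterministically so neither community is
favored.  Edges are drawn uniformly within their block pattern with
rejection of repeated-vertex draws and duplicates, so the output is always
simple and the construction is O(n log n)-ish rather than an explicit
sweep over all Θ(n³) candidate edges.  These defaults (n = 200, average
degree 5 per edge size) are the standard benchmark conditions for sparse
hypergraph detectability studies.

**Modified DCHSBM.**  N vertices in fixed clusters (default 50+50);
propensities θ_v = 1/r_v with r_v uniform on {1..24} (an explicit θ vector
may be supplied instead, e.g. for closed-form checks of the thinning
probability).  For every size-2 and size-3 sub-multiset R of the vertices,
X_R ~ Poisson(Π_{v∈R} θ_v · Ω(R)) with the all-or-nothing intensity
Ω = 1 if R lies within one cluster, else 0.1; R is included once iff
X_R > 0.  Edges supported on a single vertex ({v,v} or {v,v,v}) are
replaced by the dyad {v, (v+1) mod N} — the generalization of the stated
rule to arbitrary N — and duplicates are removed.  Mixed multiset edges
such as {v,v,u} are kept by default (`keep_multiset_edges=True`);
`simplify=True` collapses every edge to its distinct-vertex support and
dedupes, which is required before running the simple-count chain.  The
point of this generator is degree heterogeneity that is *uninformative* of
the clusters; under the defaults the top/bottom degree-decile ratio
exceeds 5 in every pilot draw.

A caveat established during validation: under these parameters the
realized instances carry roughly 30–160 2-edges and 80–650 3-edges
(200-draw pilot), i.e. mean degree ~6–13.  At that sparsity the planted
partition is typically *not* the global entropy minimizer — multi-run
annealing finds assignments with strictly lower log Z than the ground
truth, and isolated vertices occur — so the degree-corrected chain's ARI
on this family plateaus around 0.7–0.9 rather than 1.0, while the
non-corrected chain stays at chance.  The qualitative degree-correction
contrast is robust at every seed tested; exact recovery would require a
denser parameterization.

## Projections and baseline

Clique projections connect distinct co-occurring vertices: the simple
projection clamps pair multiplicities to 1, the multi-edge projection
keeps one dyad per co-occurring hyperedge (parallel hyperedges each
count).  Repeated-vertex incidences within one hyperedge never emit
self-loops.  The spectral baseline is a thin comparator wrapper around
scikit-learn's normalized-Laplacian `SpectralClustering` on the
multiplicity-weighted adjacency (k-means label assignment, fixed
random_state); isolated vertices are excluded from the decomposition and
assigned to the largest recovered cluster.  It is a comparator, not part
of the method.

## Test design and problem sizes

Expected values in the tests come from independent routes: exhaustive
enumeration of all candidate hypergraphs for the simple/multiset counts at
n ≤ 5, brute-force stub matchings for the degree-corrected count, the
a(γ)·c(γ) factorization versus the closed form, full recomputation against
incremental deltas (10⁻⁹), and a hand contingency-table ARI against the
scikit-learn implementation.  End-to-end experiments run at the benchmark
scale (planted n = 200 per community, best of 20 runs of 20 000 steps;
DCHSBM 100 vertices, best of 10) and the signal-plane sweep at an 11×11
grid with n = 60, 2 replicates and 5 attempts per pixel — small enough to
re-run routinely while preserving the corner/center/monotonicity pattern;
the paper-scale 51×51 sweep remains available behind `hypermi sweep
--full`.  What passing synthetic tests do *not* show: real contact or
draft data have overlapping communities, skewed edge-size mixes and
token-level noise that the generators do not emulate; performance there
must be assessed on the data itself via the generic hyperedge-list reader.

## Known limitations

Single-vertex moves only (no merge-split), so very large m landscapes mix
slowly; the degree-corrected count is stub-approximate; weighted
hyperedges and incidence-matrix interchange formats are out of scope; the
annealer assumes the label budget m is given (or chosen via `select_m`).
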