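# hypermi

Hypergraph community detection by compression-entropy minimization, with
degree correction, simulated annealing, minimum-description-length model
selection, clique projections and planted-partition benchmark generators.

## The problem and the method

Many relational data sets — contact groups, co-purchases, card pools —
are *hypergraphs*: their edges join two, three, or more vertices at once.
`hypermi` clusters such data by treating a candidate partition as a lossy
**compression** of the hypergraph and asking how informative that
compression is about the original structure.

Formally, a compression of a hypergraph H into m clusters is
γ = ({C_i}, {e_λ}), the cluster memberships together with the number e_λ
of edges of each λ-type, where λ_i = |A ∩ C_i| records how an edge A
intersects the clusters.  Let Z(γ) be the number of hypergraphs compatible
with γ.  Maximizing the mutual information between the hypergraph and its
compressed description is equivalent to minimizing the conditional entropy

    H(H | γ) = log Z(γ),

so the clustering task becomes: find the assignment vector **c** whose
induced compression is compatible with the fewest alternative hypergraphs.
This is also maximum-likelihood inference in a microcanonical hypergraph
stochastic blockmodel.  Four counting models for Z(γ) are implemented:

* **simple** — simple hypergraphs: Z = Π_λ C(N_λ, e_λ), N_λ = Π_i C(|C_i|, λ_i);
* **multiset** — edge selections with repetition: Z = Π_λ N_λ^{e_λ};
* **degree_corrected** — the compression additionally carries the degree
  sequence, counted by matching distinguishable degree "stubs" into packets
  and edges: Z = Π_i e_i! / (Π_λ e_λ! · Π_λ Π_i (λ_i!)^{e_λ}), with e_i the
  degree sum of cluster i.  Degree correction stops heterogeneous degrees
  from masquerading as community structure;
* **graph** — the module-matrix count for 2-uniform inputs (to which the
  simple count reduces on graphs).

Minimization is by Metropolis–Hastings simulated annealing over
single-vertex relabelings with the linear schedule β(t) = (t+1)·10⁻⁴,
tracking the best assignment seen; production runs keep the best of R
independent restarts.  When the number of clusters is unknown,
`select_m` picks it by minimum description length,
L = n·log₂ m + Σ_k C(m+k−1, k)·log₂ ℓ_k + log₂ Z(γ)  (bits).

## Worked example

Generate a planted-partition hypergraph whose community signal lives
*only* in the 3-edges (p₂ = 1 means every 2-edge is within a community;
p₃ = 0 means every 3-edge straddles both), cluster it, and score against
the planted labels:

```sh
hypermi generate planted --n 200 --p2 1.0 --p3 0.0 --seed 1 \
        --out h.hyperedges --labels truth.tsv
hypermi cluster h.hyperedges --m 2 --runs 20 --seed 1 \
        --out pred.tsv --summary summary.json
# best entropy (nats): 16826.832277
hypermi score --pred pred.tsv --truth truth.tsv
# 1.000000
```

The clustering attains ARI 1.0 — perfect recovery of the two planted
200-vertex communities — at a best compression entropy of 16 826.8 nats
(24 276.0 bits, also reported in `summary.json`).  Spectral clustering of
the same hypergraph's simple clique projection scores ARI ≈ 0 here: the
projection discards the edge-size information that carries the signal.
The same pipeline is available as library calls
(`hypermi.planted_partition`, `hypermi.multi_run`,
`hypermi.adjusted_rand_index`).

Other subcommands: `hypermi generate dchsbm` (degree-heterogeneous
blockmodel), `hypermi project --mode simple|multi` (clique projections),
`hypermi select-m` (MDL choice of m), `hypermi sweep` (ARI heatmap over
the (p₂, p₃) plane).

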