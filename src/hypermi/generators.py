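"""Synthetic hypergraph benchmark generators with planted community labels.

Two models:

* :func:`planted_partition` — two equal communities of size n; exactly 5n
  2-edges and round(10n/3) 3-edges (so each vertex sees on average five
  2-edges and five 3-edges), with the proportion of within-community 2-edges
  and 3-edges controlled by p₂ and p₃.  Output is simple by construction.
* :func:`dchsbm` — a modified degree-corrected hypergraph stochastic
  blockmodel: per-vertex propensities θ_v = 1/r_v with r_v uniform on
  {1..r_max}, and for every size-2/3 sub-multiset R of the vertices an
  all-or-nothing intensity Ω(R) (ω_in if R lies in one cluster, else ω_out);
  R becomes an edge (once) iff a Poisson(Π_{v∈R} θ_v · Ω(R)) draw is
  positive.  Edges supported on a single vertex are replaced by the dyad
  {v, (v+1) mod N}.  Degree heterogeneity here is deliberately uninformative
  of the planted clusters — the point of the degree-correction experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np

from .core import Assignment, Hypergraph

__all__ = [
    "PlantedPartitionConfig",
    "DCHSBMConfig",
    "planted_partition",
    "dchsbm",
]

_MAX_TRIES = 200


@dataclass(frozen=True)
class PlantedPartitionConfig:
    """Planted-partition settings: two communities of ``n`` vertices each."""

    n: int
    p2: float
    p3: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if not (0.0 <= self.p2 <= 1.0 and 0.0 <= self.p3 <= 1.0):
            raise ValueError("p2 and p3 must lie in [0, 1]")

    @property
    def n2(self) -> int:
        """Total number of 2-edges: exactly 5n."""
        return 5 * self.n

    @property
    def n3(self) -> int:
        """Total number of 3-edges: round(10n/3)."""
        return int(round(10 * self.n / 3))


def _sample_distinct(rng: np.random.Generator, pools: Sequence[np.ndarray],
                     used: set, budget: int) -> tuple[int, ...]:
    """Draw one vertex per pool entry, all distinct, not colliding with used."""
    for _ in range(budget):
        edge = tuple(sorted(int(rng.choice(p)) for p in pools))
        if len(set(edge)) == len(edge) and edge not in used:
            return edge
    raise RuntimeError("rejection sampling failed; communities too small "
                       "for the requested edge counts")


def planted_partition(config: PlantedPartitionConfig) -> tuple[Hypergraph, Assignment]:
    """Sample a planted-partition hypergraph and its ground-truth labels.

    Within-community edges are split as evenly as possible between the two
    communities; cross 3-edges alternate their majority side so neither
    community is systematically favored.  All edges have distinct vertices
    and no edge is duplicated (rejection sampling), so the output is simple.
    """
    n = config.n
    rng = np.random.default_rng(config.seed)
    comm = [np.arange(n), np.arange(n, 2 * n)]
    used: set = set()
    edges: list[tuple[int, ...]] = []
    budget = _MAX_TRIES * max(config.n2, config.n3)

    def emit(pools):
        e = _sample_distinct(rng, pools, used, budget)
        used.add(e)
        edges.append(e)

    w2 = int(round(config.p2 * config.n2))
    for k in range(w2):
        side = comm[k % 2]
        emit([side, side])
    for _ in range(config.n2 - w2):
        emit([comm[0], comm[1]])

    w3 = int(round(config.p3 * config.n3))
    for k in range(w3):
        side = comm[k % 2]
        emit([side, side, side])
    for k in range(config.n3 - w3):
        major, minor = comm[k % 2], comm[1 - k % 2]
        emit([major, major, minor])

    h = Hypergraph.from_edges(edges, n=2 * n)
    truth = Assignment(np.repeat([0, 1], n), m=2)
    return h, truth


@dataclass(frozen=True)
class DCHSBMConfig:
    """Modified degree-corrected HSBM settings."""

    cluster_sizes: tuple[int, ...] = (50, 50)
    r_max: int = 24
    omega_in: float = 1.0
    omega_out: float = 0.1
    seed: int = 0
    #: keep residual multiset edges like {v,v,u} as-is; set False to collapse
    keep_multiset_edges: bool = True
    #: explicit per-vertex propensities overriding the 1/r_v draw (testing/controls)
    theta: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")
        if not (self.omega_in > self.omega_out >= 0):
            raise ValueError("need omega_in > omega_out >= 0")
        if self.theta is not None:
            if len(self.theta) != sum(self.cluster_sizes):
                raise ValueError("theta length must equal the vertex count")
            if any(not (0 < t <= 1) for t in self.theta):
                raise ValueError("theta entries must lie in (0, 1]")


def dchsbm(config: DCHSBMConfig, simplify: bool = False) -> tuple[Hypergraph, Assignment]:
    """Sample from the modified DCHSBM; returns (hypergraph, planted labels).

    With ``simplify=True`` every edge is collapsed to its distinct-vertex
    support and duplicates are removed, yielding a simple hypergraph suitable
    for the non-corrected (simple-count) entropy chain.  Otherwise only exact
    duplicate edges are removed, and mixed multiset edges (≥2 distinct
    vertices, e.g. {v,v,u}) survive per ``keep_multiset_edges``.
    """
    N = int(sum(config.cluster_sizes))
    rng = np.random.default_rng(config.seed)
    labels = np.repeat(np.arange(len(config.cluster_sizes)), config.cluster_sizes)

    if config.theta is None:
        r = rng.integers(1, config.r_max + 1, size=N)
        theta = 1.0 / r
    else:
        theta = np.asarray(config.theta, dtype=float)

    edges: list[tuple[int, ...]] = []
    for size in (2, 3):
        members = np.array(
            list(combinations_with_replacement(range(N), size)), dtype=np.int64
        )
        rate = theta[members].prod(axis=1)
        same = np.all(labels[members] == labels[members[:, :1]], axis=1)
        rate *= np.where(same, config.omega_in, config.omega_out)
        hit = rng.poisson(rate) > 0
        edges.extend(tuple(row) for row in members[hit])

    # replace single-support edges {v,v} / {v,v,v} by the dyad {v, v+1 mod N}
    replaced: list[tuple[int, ...]] = []
    for e in edges:
        if len(set(e)) == 1:
            v = e[0]
            replaced.append(tuple(sorted((v, (v + 1) % N))))
        else:
            replaced.append(e)

    if simplify or not config.keep_multiset_edges:
        replaced = [tuple(sorted(set(e))) for e in replaced]
    # deduplicate (multiset equality == sorted-tuple equality), keep order
    seen: set = set()
    final: list[tuple[int, ...]] = []
    for e in replaced:
        if e not in seen:
            seen.add(e)
            final.append(e)

    h = Hypergraph.from_edges(final, n=N)
    truth = Assignment(labels, m=len(config.cluster_sizes))
    return h, truth
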