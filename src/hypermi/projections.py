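"""Clique projections from hypergraphs to 2-uniform (multi)graphs.

The simple projection joins every pair of distinct vertices that co-occur in
at least one hyperedge by a single dyadic edge; the multi-edge projection
keeps one dyadic edge per co-occurring hyperedge.  Both are lossy: edges of
size > 2 are flattened into their pairwise shadows.  Repeated-vertex
incidences inside one hyperedge never emit self-loops.
"""

from __future__ import annotations

from itertools import combinations

from .core import Hypergraph

__all__ = ["simple_projection", "multiedge_projection"]


def _pair_multiplicities(h: Hypergraph) -> dict[tuple[int, int], int]:
    pairs: dict[tuple[int, int], int] = {}
    for e in h.edges:
        distinct = sorted(set(e))
        for u, v in combinations(distinct, 2):
            pairs[(u, v)] = pairs.get((u, v), 0) + 1
    return pairs


def simple_projection(h: Hypergraph) -> Hypergraph:
    """2-uniform simple graph: {u,v} present iff u≠v co-occur in some edge."""
    pairs = sorted(_pair_multiplicities(h))
    return Hypergraph(h.vertex_tokens, tuple(pairs))


def multiedge_projection(h: Hypergraph) -> Hypergraph:
    """2-uniform multigraph: multiplicity of {u,v} = #hyperedges containing both."""
    mult = _pair_multiplicities(h)
    edges = []
    for pair in sorted(mult):
        edges.extend([pair] * mult[pair])
    return Hypergraph(h.vertex_tokens, tuple(edges))
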