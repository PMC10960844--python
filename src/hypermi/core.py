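"""Hypergraph and partition data model, λ-types, compressions, and file I/O.

A hypergraph is a vertex set together with a collection of edges, each edge a
multiset of vertices.  A *compression* of a hypergraph into ``m`` clusters is a
lossy summary: the cluster sizes plus, for every λ-type (the vector of
edge/cluster intersection counts), the number of edges of that type — and
optionally the vertex degree sequence (the degree-corrected variant).  These
summaries are what the entropy objective is computed from.

Internal cluster labels and vertex indices are dense 0-based integers; external
I/O preserves user-supplied vertex tokens.  Edges are stored as sorted tuples of
vertex indices, so multiset equality is tuple equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Hypergraph",
    "Assignment",
    "LambdaType",
    "Compression",
    "ModuleMatrix",
    "lambda_type",
    "compress",
    "module_matrix",
    "read_hyperedge_list",
    "write_hyperedge_list",
    "read_partition",
    "write_partition",
]

#: canonical λ-type: sorted tuple of (cluster index, positive count) pairs
LambdaType = tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class Hypergraph:
    """A (multi)hypergraph with dense integer vertices.

    Attributes
    ----------
    vertex_tokens:
        External identifiers, position ``v`` naming internal vertex ``v``.
    edges:
        Each edge a sorted tuple of vertex indices; repeats encode multiset
        multiplicity.
    """

    vertex_tokens: tuple[str, ...]
    edges: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.vertex_tokens)
        for k, e in enumerate(self.edges):
            if len(e) < 1:
                raise ValueError(f"edge {k} is empty")
            if any(v < 0 or v >= n for v in e):
                raise ValueError(f"edge {k} has vertex index outside [0, {n})")
            if tuple(sorted(e)) != tuple(e):
                raise ValueError(f"edge {k} is not stored sorted")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Iterable[int]],
        n: int | None = None,
        vertex_tokens: Sequence[str] | None = None,
    ) -> "Hypergraph":
        """Build from raw integer edges; tokens default to ``str(v)``."""
        norm = tuple(tuple(sorted(e)) for e in edges)
        if vertex_tokens is None:
            if n is None:
                n = 1 + max((max(e) for e in norm), default=-1)
            vertex_tokens = tuple(str(v) for v in range(n))
        else:
            vertex_tokens = tuple(vertex_tokens)
        return cls(vertex_tokens, norm)

    @property
    def n(self) -> int:
        return len(self.vertex_tokens)

    @property
    def degrees(self) -> np.ndarray:
        """Per-vertex degree ``d_v``: total multiplicity of v across edges."""
        d = np.zeros(self.n, dtype=np.int64)
        for e in self.edges:
            for v in e:
                d[v] += 1
        return d

    @property
    def is_simple(self) -> bool:
        """True iff no edge repeats a vertex and no two edges are equal."""
        seen = set()
        for e in self.edges:
            if len(set(e)) != len(e) or e in seen:
                return False
            seen.add(e)
        return True

    @property
    def edge_sizes(self) -> np.ndarray:
        return np.array([len(e) for e in self.edges], dtype=np.int64)

    def is_uniform(self, k: int) -> bool:
        return all(len(e) == k for e in self.edges)


@dataclass(frozen=True)
class Assignment:
    """Cluster labels ``c`` with a label budget ``m``; empty clusters allowed."""

    c: np.ndarray
    m: int

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=np.int64)
        object.__setattr__(self, "c", c)
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if c.size and (c.min() < 0 or c.max() >= self.m):
            raise ValueError("labels must lie in [0, m)")

    @property
    def n(self) -> int:
        return int(self.c.size)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.c, minlength=self.m).astype(np.int64)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Assignment)
            and self.m == other.m
            and np.array_equal(self.c, other.c)
        )


def lambda_type(edge: Sequence[int], assignment: Assignment) -> LambdaType:
    """λ-type of an edge: λ_i = |A ∩ C_i| counted with multiplicity.

    Returned in canonical form: sorted tuple of (cluster, count) pairs with
    zero entries omitted, so Σ counts = |A|.
    """
    counts: dict[int, int] = {}
    c = assignment.c
    for v in edge:
        i = int(c[v])
        counts[i] = counts.get(i, 0) + 1
    return tuple(sorted(counts.items()))


@dataclass(frozen=True)
class Compression:
    """Summary γ = (cluster sizes, λ-type edge counts[, degrees])."""

    cluster_sizes: np.ndarray
    e_lambda: Mapping[LambdaType, int]
    degrees: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cluster_sizes", np.asarray(self.cluster_sizes, dtype=np.int64)
        )
        if self.degrees is not None:
            object.__setattr__(
                self, "degrees", np.asarray(self.degrees, dtype=np.int64)
            )
        for lam, cnt in self.e_lambda.items():
            if cnt < 0:
                raise ValueError("negative e_lambda count")
            if any(x < 1 for _, x in lam):
                raise ValueError(f"λ-type {lam} stores a nonpositive count")

    @property
    def m(self) -> int:
        return int(self.cluster_sizes.size)

    @property
    def n_edges(self) -> int:
        return int(sum(self.e_lambda.values()))

    def cluster_degree_sums(self) -> np.ndarray:
        """e_i = Σ_λ λ_i e_λ, the degree sum placed in each cluster."""
        e = np.zeros(self.m, dtype=np.int64)
        for lam, cnt in self.e_lambda.items():
            for i, lam_i in lam:
                e[i] += lam_i * cnt
        return e


def compress(
    h: Hypergraph, assignment: Assignment, with_degrees: bool = False
) -> Compression:
    """Compress ``h`` under ``assignment``; optionally carry the degrees."""
    if assignment.n != h.n:
        raise ValueError("assignment length does not match hypergraph order")
    e_lambda: dict[LambdaType, int] = {}
    for e in h.edges:
        lam = lambda_type(e, assignment)
        e_lambda[lam] = e_lambda.get(lam, 0) + 1
    return Compression(
        cluster_sizes=assignment.cluster_sizes(),
        e_lambda=e_lambda,
        degrees=h.degrees if with_degrees else None,
    )


@dataclass(frozen=True)
class ModuleMatrix:
    """Symmetric m×m matrix of pairwise edge counts for a 2-uniform input."""

    M: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=np.int64)
        object.__setattr__(self, "M", M)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("module matrix must be square")
        if not np.array_equal(M, M.T):
            raise ValueError("module matrix must be symmetric")
        if (M < 0).any():
            raise ValueError("module matrix entries must be nonnegative")

    @property
    def m(self) -> int:
        return int(self.M.shape[0])

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.M).sum())


def module_matrix(h: Hypergraph, assignment: Assignment) -> ModuleMatrix:
    """Pairwise edge counts between clusters; requires every edge of size 2."""
    if assignment.n != h.n:
        raise ValueError("assignment length does not match hypergraph order")
    M = np.zeros((assignment.m, assignment.m), dtype=np.int64)
    for k, e in enumerate(h.edges):
        if len(e) != 2:
            raise ValueError(f"edge {k} has size {len(e)}, expected 2")
        i, j = int(assignment.c[e[0]]), int(assignment.c[e[1]])
        M[i, j] += 1
        if i != j:
            M[j, i] += 1
    return ModuleMatrix(M)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_hyperedge_list(source: IO[str], dialect: str = "whitespace") -> Hypergraph:
    """Read a hyperedge-list text stream: one edge per line.

    Tokens are separated by runs of whitespace (or commas in the ``comma``
    dialect); ``#`` lines are comments and blank lines are ignored.  Vertex
    tokens are mapped to dense indices in first-appearance order; a token
    repeated on one line is kept as multiset multiplicity.
    """
    if dialect not in ("whitespace", "comma"):
        raise ValueError(f"unknown dialect {dialect!r}")
    index: dict[str, int] = {}
    edges: list[tuple[int, ...]] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = (
            [t.strip() for t in line.split(",")] if dialect == "comma" else line.split()
        )
        if any(not t for t in tokens):
            raise ValueError(f"line {lineno}: malformed (empty token)")
        edge = []
        for t in tokens:
            if t not in index:
                index[t] = len(index)
            edge.append(index[t])
        edges.append(tuple(sorted(edge)))
    if not edges:
        raise ValueError("no edges")
    tokens_ordered = tuple(sorted(index, key=index.__getitem__))
    return Hypergraph(tokens_ordered, tuple(edges))


def write_hyperedge_list(h: Hypergraph, sink: IO[str]) -> None:
    """Write the hyperedge-list text format (whitespace dialect)."""
    for e in h.edges:
        sink.write(" ".join(h.vertex_tokens[v] for v in e) + "\n")


def write_partition(
    assignment: Assignment, vertex_tokens: Sequence[str], sink: IO[str]
) -> None:
    """Write a two-column TSV ``token<TAB>label``."""
    if len(set(vertex_tokens)) != len(vertex_tokens):
        raise ValueError("vertex tokens must be unique")
    if len(vertex_tokens) != assignment.n:
        raise ValueError("token count does not match assignment length")
    for v, tok in enumerate(vertex_tokens):
        sink.write(f"{tok}\t{int(assignment.c[v])}\n")


def read_partition(
    source: IO[str], vertex_tokens: Sequence[str], m: int | None = None
) -> Assignment:
    """Read a two-column TSV back into an Assignment over ``vertex_tokens``.

    Every vertex must be labeled exactly once.  ``m`` defaults to
    ``max(label)+1``.
    """
    index = {t: v for v, t in enumerate(vertex_tokens)}
    if len(index) != len(vertex_tokens):
        raise ValueError("vertex tokens must be unique")
    labels: dict[int, int] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two columns")
        tok, lab = parts
        if tok == "vertex" and lab == "cluster":  # optional header
            continue
        if tok not in index:
            raise ValueError(f"line {lineno}: unknown token {tok!r}")
        v = index[tok]
        if v in labels:
            raise ValueError(f"line {lineno}: duplicate token {tok!r}")
        labels[v] = int(lab)
    if len(labels) != len(vertex_tokens):
        missing = [t for t, v in index.items() if v not in labels]
        raise ValueError(f"partition incomplete: {len(missing)} unlabeled vertices")
    c = np.array([labels[v] for v in range(len(vertex_tokens))], dtype=np.int64)
    return Assignment(c, m=int(c.max()) + 1 if m is None else m)
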