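"""Compression entropy log Z(γ) under each counting model, with fast deltas.

Z(γ) is the number of hypergraphs compatible with a compression γ; log Z is the
conditional entropy of the hypergraph given its compressed description, and the
clustering objective is to minimize it.  Four counting models are supported:

``simple``
    Count of simple hypergraphs:  Z = Π_λ C(N_λ, e_λ)  with
    N_λ = Π_i C(|C_i|, λ_i) the number of possible λ-type edges.
``multiset``
    Count of edge selections with repetition allowed:  Z = Π_λ N_λ^{e_λ}.
``degree_corrected``
    Stub-matching count with the degree sequence part of the compression:
    Z = Π_i e_i! / (Π_λ e_λ! · Π_λ Π_i (λ_i!)^{e_λ}),
    where e_i is the degree sum of cluster i.  This counts configurations of
    distinguishable stubs grouped into packets and combined into edges; it is
    an approximation that allows repeated vertex inclusions and parallel
    edges, accurate in the large sparse limit.
``graph``
    Module-matrix count for simple 2-uniform inputs:
    Z = Π_{i<j} C(|C_i||C_j|, M_ij) · Π_i C(C(|C_i|,2), M_ii).

All values are natural-log; conversion to bits happens only in model
selection.  Factorials and binomials go through log-gamma — counts overflow
integers already at a few hundred vertices.

:class:`EntropyState` keeps a live compression (λ-type counts, cluster sizes,
cluster degree sums) for one assignment and computes the change in log Z under
a single-vertex relabel in O(deg(v)·max|A| + #realized λ-types), which is what
makes the annealer's ~10^6 evaluations affordable.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Sequence

import numpy as np

from .core import (
    Assignment,
    Compression,
    Hypergraph,
    LambdaType,
    ModuleMatrix,
    compress,
    lambda_type,
    module_matrix,
)

__all__ = [
    "EntropyModel",
    "log_comb",
    "log_z_simple",
    "log_z_multiset",
    "log_z_degree_corrected",
    "log_z_graph",
    "log_z",
    "EntropyState",
]

_LGAMMA = math.lgamma
_LOG = math.log

# above this base the lgamma difference loses absolute precision (error grows
# like N·log N·eps), so switch to the exact k-term sum-of-logs form
_BIG = 10**6


class EntropyModel(str, Enum):
    SIMPLE = "simple"
    MULTISET = "multiset"
    DEGREE_CORRECTED = "degree_corrected"
    GRAPH = "graph"


def _lfact(k: int) -> float:
    """log k! via log-gamma."""
    return _LGAMMA(k + 1)


def log_comb(N: int, k: int) -> float:
    """log C(N, k) for integer N (possibly a huge Python int) and small k.

    Raises ValueError when k > N (an infeasible count).
    """
    if k < 0 or k > N:
        raise ValueError(f"infeasible binomial C({N}, {k})")
    if k == 0 or k == N:
        return 0.0
    if N < _BIG:
        return _LGAMMA(N + 1) - _LGAMMA(k + 1) - _LGAMMA(N - k + 1)
    # exact alternating form for huge N: log C(N,k) = Σ_{j<k} log(N-j) - log k!
    return sum(_LOG(N - j) for j in range(k)) - _LGAMMA(k + 1)


def _n_lambda(lam: LambdaType, sizes: Sequence[int]) -> int:
    """N_λ = Π_i C(|C_i|, λ_i): the number of possible λ-type edges."""
    out = 1
    for i, lam_i in lam:
        out *= math.comb(int(sizes[i]), lam_i)
    return out


def log_z_simple(compression: Compression) -> float:
    """log of the simple-hypergraph count  Σ_λ log C(N_λ, e_λ)  (≥ 0)."""
    sizes = compression.cluster_sizes
    total = 0.0
    for lam, e in compression.e_lambda.items():
        if e == 0:
            continue
        n_lam = _n_lambda(lam, sizes)
        if e > n_lam:
            raise ValueError(
                "compression infeasible for simple model: "
                f"e_λ={e} > N_λ={n_lam} for λ={lam} "
                "(input has multi-edges or multiset edges)"
            )
        total += log_comb(n_lam, e)
    return total


def log_z_multiset(compression: Compression) -> float:
    """log of the multi-hypergraph count  Σ_λ e_λ Σ_i log C(|C_i|, λ_i)."""
    sizes = compression.cluster_sizes
    total = 0.0
    for lam, e in compression.e_lambda.items():
        if e == 0:
            continue
        for i, lam_i in lam:
            if lam_i > sizes[i]:
                raise ValueError(
                    f"λ_i={lam_i} exceeds cluster size {sizes[i]} (cluster {i})"
                )
            total += e * log_comb(int(sizes[i]), lam_i)
    return total


def _lambda_lfact_sum(lam: LambdaType) -> float:
    """S(λ) = Σ_i log λ_i!."""
    return sum(_lfact(lam_i) for _, lam_i in lam)


def log_z_degree_corrected(compression: Compression) -> float:
    """log of the stub-matching count:  Σ_i log e_i! − Σ_λ log e_λ! − Σ_λ e_λ S(λ)."""
    if compression.degrees is None:
        raise ValueError("degree-corrected model requires degree sequence")
    e_i = compression.cluster_degree_sums()
    total = float(sum(_lfact(int(x)) for x in e_i))
    for lam, e in compression.e_lambda.items():
        if e == 0:
            continue
        total -= _lfact(e) + e * _lambda_lfact_sum(lam)
    return total


def log_a_factor(compression: Compression) -> float:
    """log a(γ): stub-to-λ-type assignments, Π_i multinomial(e_i; …, λ_i e_λ, …)."""
    e_i = compression.cluster_degree_sums()
    total = float(sum(_lfact(int(x)) for x in e_i))
    for lam, e in compression.e_lambda.items():
        if e == 0:
            continue
        for _, lam_i in lam:
            total -= _lfact(lam_i * e)
    return total


def log_c_factor(compression: Compression) -> float:
    """log c(γ): packet groupings combined into edges,
    Π_λ (e_λ!)^{-1} Π_i multinomial(λ_i e_λ; λ_i, …, λ_i)."""
    total = 0.0
    for lam, e in compression.e_lambda.items():
        if e == 0:
            continue
        total -= _lfact(e)
        for _, lam_i in lam:
            total += _lfact(lam_i * e) - e * _lfact(lam_i)
    return total


def log_z_graph(mm: ModuleMatrix, cluster_sizes: Sequence[int]) -> float:
    """log of the module-matrix graph count."""
    sizes = [int(s) for s in cluster_sizes]
    if len(sizes) != mm.m:
        raise ValueError("cluster_sizes length does not match module matrix")
    M = mm.M
    total = 0.0
    for i in range(mm.m):
        n_ii = math.comb(sizes[i], 2)
        if M[i, i] > n_ii:
            raise ValueError(f"infeasible within-cluster count M[{i},{i}]={M[i, i]}")
        total += log_comb(n_ii, int(M[i, i]))
        for j in range(i + 1, mm.m):
            n_ij = sizes[i] * sizes[j]
            if M[i, j] > n_ij:
                raise ValueError(f"infeasible cross count M[{i},{j}]={M[i, j]}")
            total += log_comb(n_ij, int(M[i, j]))
    return total


def _check_model(h: Hypergraph, model: EntropyModel) -> None:
    model = EntropyModel(model)
    if model is EntropyModel.SIMPLE and not h.is_simple:
        raise ValueError("simple model requires a simple hypergraph")
    if model is EntropyModel.MULTISET and any(
        len(set(e)) != len(e) for e in h.edges
    ):
        raise ValueError("multiset model requires edges without repeated vertices")
    if model is EntropyModel.GRAPH:
        if not h.is_uniform(2):
            raise ValueError("graph model requires a 2-uniform hypergraph")
        if not h.is_simple:
            raise ValueError("graph model requires a simple (multi-edge free) graph")


def log_z(h: Hypergraph, assignment: Assignment, model: EntropyModel) -> float:
    """From-scratch log Z of ``h`` under ``assignment`` for the given model."""
    model = EntropyModel(model)
    _check_model(h, model)
    if model is EntropyModel.GRAPH:
        return log_z_graph(module_matrix(h, assignment), assignment.cluster_sizes())
    comp = compress(h, assignment, with_degrees=model is EntropyModel.DEGREE_CORRECTED)
    if model is EntropyModel.SIMPLE:
        return log_z_simple(comp)
    if model is EntropyModel.MULTISET:
        return log_z_multiset(comp)
    return log_z_degree_corrected(comp)


# ---------------------------------------------------------------------------
# Incremental state for single-vertex moves
# ---------------------------------------------------------------------------

class EntropyState:
    """Live compression bookkeeping for one assignment under one model.

    λ-types are interned to integer ids; per-edge current type ids, per-type
    counts, cluster sizes, cluster degree sums and the cached log Z are kept
    in sync.  :meth:`delta` evaluates a single-vertex relabel without
    mutating; :meth:`apply` commits it.  Type transitions
    (type, from-cluster, to-cluster, multiplicity) are memoized, which makes
    the degree-corrected path — whose contribution per type is
    −log e_λ! − e_λ·S(λ) plus the two cluster degree-sum terms — a handful of
    table lookups per incident edge.
    """

    def __init__(
        self,
        h: Hypergraph,
        assignment: Assignment,
        model: EntropyModel = EntropyModel.DEGREE_CORRECTED,
    ):
        self.model = EntropyModel(model)
        _check_model(h, self.model)
        self.h = h
        self.m = assignment.m
        self.labels = np.array(assignment.c, dtype=np.int64)
        self.sizes = assignment.cluster_sizes().tolist()
        self.degrees = h.degrees
        self.e_i = [0] * self.m

        # λ-type registry
        self._type_index: dict[LambdaType, int] = {}
        self._types: list[LambdaType] = []
        self._type_S: list[float] = []  # S(λ) = Σ_i log λ_i!
        self._counts: list[int] = []
        self._trans: dict[tuple[int, int, int, int], int] = {}

        self.edge_type = np.empty(len(h.edges), dtype=np.int64)
        self.incidence: list[list[tuple[int, int]]] = [[] for _ in range(h.n)]
        asg = Assignment(self.labels, self.m)
        for k, e in enumerate(h.edges):
            tid = self._intern(lambda_type(e, asg))
            self._counts[tid] += 1
            self.edge_type[k] = tid
            mult: dict[int, int] = {}
            for v in e:
                mult[v] = mult.get(v, 0) + 1
            for v, mu in mult.items():
                self.incidence[v].append((k, mu))
        for lam, cnt in zip(self._types, self._counts):
            for i, lam_i in lam:
                self.e_i[i] += lam_i * cnt

        # lgamma(k+1) table up to the largest count the state can ever hold
        top = max(int(self.degrees.sum()), len(h.edges), max(self.sizes, default=1)) + 2
        self._lgf = np.array([_LGAMMA(k + 1) for k in range(top)])

        self._log_z = self._summary_log_z(self._all_type_items(), self.sizes, self.e_i)
        self._steps_since_resync = 0

    # -- registry -----------------------------------------------------------

    def _intern(self, lam: LambdaType) -> int:
        tid = self._type_index.get(lam)
        if tid is None:
            tid = len(self._types)
            self._type_index[lam] = tid
            self._types.append(lam)
            self._type_S.append(_lambda_lfact_sum(lam))
            self._counts.append(0)
        return tid

    def _transition(self, tid: int, a: int, b: int, mu: int) -> int:
        """Type id after moving ``mu`` incidences from cluster a to cluster b."""
        key = (tid, a, b, mu)
        out = self._trans.get(key)
        if out is None:
            d = dict(self._types[tid])
            d[a] = d.get(a, 0) - mu
            if d[a] == 0:
                del d[a]
            elif d[a] < 0:
                raise ValueError("inconsistent λ-type transition")
            d[b] = d.get(b, 0) + mu
            out = self._intern(tuple(sorted(d.items())))
            self._trans[key] = out
        return out

    def _all_type_items(self):
        return [
            (lam, cnt) for lam, cnt in zip(self._types, self._counts) if cnt > 0
        ]

    # -- objective ----------------------------------------------------------

    @property
    def log_z_cached(self) -> float:
        return self._log_z

    def _summary_log_z(self, items, sizes, e_i) -> float:
        model = self.model
        if model is EntropyModel.DEGREE_CORRECTED:
            total = float(sum(_lfact(int(x)) for x in e_i))
            for lam, cnt in items:
                total -= _lfact(cnt) + cnt * _lambda_lfact_sum(lam)
            return total
        total = 0.0
        if model is EntropyModel.MULTISET:
            for lam, cnt in items:
                for i, lam_i in lam:
                    total += cnt * log_comb(int(sizes[i]), lam_i)
            return total
        # simple / graph share the per-type binomial count
        for lam, cnt in items:
            n_lam = _n_lambda(lam, sizes)
            if cnt > n_lam:
                raise ValueError("compression infeasible for simple model")
            total += log_comb(n_lam, cnt)
        return total

    def recompute(self) -> float:
        """From-scratch log Z of the current labels (audit path)."""
        return log_z(self.h, Assignment(self.labels.copy(), self.m), self.model)

    # -- single-vertex moves ------------------------------------------------

    def delta(self, v: int, b: int):
        """Return (Δ log Z, move-info) for relabeling vertex v to cluster b."""
        a = int(self.labels[v])
        if a == b:
            return 0.0, None
        changes: dict[int, int] = {}
        moved: list[tuple[int, int]] = []
        for eid, mu in self.incidence[v]:
            t_old = int(self.edge_type[eid])
            t_new = self._transition(t_old, a, b, mu)
            changes[t_old] = changes.get(t_old, 0) - 1
            changes[t_new] = changes.get(t_new, 0) + 1
            moved.append((eid, t_new))
        d_v = int(self.degrees[v])

        if self.model is EntropyModel.DEGREE_CORRECTED:
            lgf = self._lgf
            e_a, e_b = self.e_i[a], self.e_i[b]
            delta = (
                lgf[e_a - d_v] - lgf[e_a] + lgf[e_b + d_v] - lgf[e_b]
            )
            counts = self._counts
            S = self._type_S
            for tid, dc in changes.items():
                if dc:
                    n_old = counts[tid]
                    delta -= lgf[n_old + dc] - lgf[n_old] + dc * S[tid]
            delta = float(delta)
            return delta, (a, b, changes, moved, d_v, self._log_z + delta)

        # size-dependent models: recompute the summary over all realized
        # types under old and new sizes/counts (the realized-type set is small)
        new_sizes = list(self.sizes)
        new_sizes[a] -= 1
        new_sizes[b] += 1
        old_total = self._log_z
        items = []
        for tid, cnt in enumerate(self._counts):
            cnt2 = cnt + changes.get(tid, 0)
            if cnt2 > 0:
                items.append((self._types[tid], cnt2))
        new_total = self._summary_log_z(items, new_sizes, None)
        return float(new_total - old_total), (a, b, changes, moved, d_v, new_total)

    def apply(self, v: int, b: int, info) -> None:
        """Commit a move previously evaluated by :meth:`delta`."""
        if info is None:
            return
        a, _, changes, moved, d_v, new_log_z = info
        self.labels[v] = b
        self.sizes[a] -= 1
        self.sizes[b] += 1
        self.e_i[a] -= d_v
        self.e_i[b] += d_v
        for tid, dc in changes.items():
            self._counts[tid] += dc
        for eid, t_new in moved:
            self.edge_type[eid] = t_new
        self._log_z = float(new_log_z)
        self._steps_since_resync += 1
        if self._steps_since_resync >= 8192:
            self._log_z = self._summary_log_z(
                self._all_type_items(), self.sizes, self.e_i
            )
            self._steps_since_resync = 0

    def assignment(self) -> Assignment:
        return Assignment(self.labels.copy(), self.m)
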