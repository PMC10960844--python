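import math
from itertools import combinations

import numpy as np
import pytest

from hypermi import (
    Assignment,
    Compression,
    Hypergraph,
    compress,
    log_z,
    log_z_degree_corrected,
    log_z_graph,
    log_z_multiset,
    log_z_simple,
    module_matrix,
)
from hypermi.entropy import (
    EntropyModel,
    EntropyState,
    log_a_factor,
    log_c_factor,
    log_comb,
)
from .conftest import random_assignment, random_hypergraph


def enumerate_candidate_edges(n):
    """All possible simple edges (nonempty distinct-vertex subsets) on n vertices."""
    out = []
    for k in range(1, n + 1):
        out.extend(combinations(range(n), k))
    return out


def count_simple_hypergraphs_matching(h, asg):
    """Brute force: # simple hypergraphs with |E| edges whose compression equals γ."""
    target = dict(compress(h, asg).e_lambda)
    universe = enumerate_candidate_edges(h.n)
    count = 0
    for cand in combinations(universe, len(h.edges)):
        cand_h = Hypergraph.from_edges(cand, n=h.n)
        if dict(compress(cand_h, asg).e_lambda) == target:
            count += 1
    return count


class TestSimpleCount:
    def test_three_vertices_one_edge(self):
        # one cluster of 3, one 2-edge: the 3 simple hypergraphs {a,b},{a,c},{b,c}
        c = Compression(np.array([3]), {((0, 2),): 1})
        assert log_z_simple(c) == pytest.approx(math.log(3))

    def test_zero_edges_zero_entropy(self):
        assert log_z_simple(Compression(np.array([5]), {})) == 0.0

    def test_split_edge_counts_cross_choices(self):
        # sizes (2,1), one (1,1)-edge: 2 hypergraphs
        c = Compression(np.array([2, 1]), {((0, 1), (1, 1)): 1})
        assert log_z_simple(c) == pytest.approx(math.log(2))

    def test_multi_edge_compression_rejected(self):
        c = Compression(np.array([2]), {((0, 2),): 2})  # only 1 possible edge
        with pytest.raises(ValueError, match="infeasible"):
            log_z_simple(c)

    def test_exhaustive_enumeration_oracle(self, rng):
        for _ in range(4):
            h = random_hypergraph(rng, 5, 3, sizes=(1, 2, 3))
            if not h.is_simple:
                continue
            asg = random_assignment(rng, 5, 2)
            z = math.exp(log_z_simple(compress(h, asg)))
            assert count_simple_hypergraphs_matching(h, asg) == pytest.approx(z)


class TestMultisetCount:
    def test_pair_in_cluster_of_three(self):
        c = Compression(np.array([3]), {((0, 2),): 1})
        assert log_z_multiset(c) == pytest.approx(math.log(3))

    def test_duplicate_edge_doubles_contribution(self):
        c = Compression(np.array([3]), {((0, 2),): 2})
        assert log_z_multiset(c) == pytest.approx(2 * math.log(3))

    def test_zero_edges(self):
        assert log_z_multiset(Compression(np.array([4, 2]), {})) == 0.0

    def test_oversized_lambda_rejected(self):
        c = Compression(np.array([1]), {((0, 2),): 1})
        with pytest.raises(ValueError):
            log_z_multiset(c)

    def test_per_type_enumeration_oracle(self, rng):
        # Z = Π_λ (#candidate λ-edges)^{e_λ}, candidates counted by enumeration
        for _ in range(4):
            h = random_hypergraph(rng, 5, 3, sizes=(2, 3))
            asg = random_assignment(rng, 5, 2)
            comp = compress(h, asg)
            expected = 1.0
            for lam, e in comp.e_lambda.items():
                cands = [
                    cand
                    for cand in enumerate_candidate_edges(5)
                    if dict(
                        compress(
                            Hypergraph.from_edges([cand], n=5), asg
                        ).e_lambda
                    )
                    == {lam: 1}
                ]
                expected *= len(cands) ** e
            assert math.exp(log_z_multiset(comp)) == pytest.approx(expected)


class TestDegreeCorrectedCount:
    def test_unique_stub_pairing(self):
        h = Hypergraph.from_edges([(0, 1)], n=2)
        asg = Assignment(np.array([0, 0]), 1)
        c = compress(h, asg, with_degrees=True)
        assert log_z_degree_corrected(c) == pytest.approx(0.0)

    def test_two_parallel_edges_three_matchings(self):
        # d=(2,2), two 2-edges within one cluster: 4 labeled stubs grouped into
        # 2 unordered size-2 edges; brute-force pairings of {a1,a2,b1,b2}: 3
        stubs = list(range(4))
        matchings = set()
        for p in combinations(combinations(stubs, 2), 2):
            if set(p[0]) | set(p[1]) == set(stubs):
                matchings.add(frozenset(map(frozenset, p)))
        assert len(matchings) == 3
        h = Hypergraph.from_edges([(0, 1), (0, 1)], n=2)
        c = compress(h, Assignment(np.array([0, 0]), 1), with_degrees=True)
        assert math.exp(log_z_degree_corrected(c)) == pytest.approx(3.0)

    def test_forced_configuration(self):
        h = Hypergraph.from_edges([(0, 1)], n=2)
        c = compress(h, Assignment(np.array([0, 1]), 2), with_degrees=True)
        assert log_z_degree_corrected(c) == pytest.approx(0.0)

    def test_requires_degrees(self):
        c = Compression(np.array([2]), {((0, 2),): 1})
        with pytest.raises(ValueError, match="degree sequence"):
            log_z_degree_corrected(c)

    def test_closed_form_equals_assignment_times_combination_factors(self, rng):
        # Z(γ) = a(γ)·c(γ) must hold exactly for the closed form
        for _ in range(100):
            h = random_hypergraph(rng, 8, 10, multisets=True)
            asg = random_assignment(rng, 8, 3)
            c = compress(h, asg, with_degrees=True)
            lhs = log_z_degree_corrected(c)
            rhs = log_a_factor(c) + log_c_factor(c)
            assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_invariant_under_within_cluster_degree_permutation(self, rng):
        # entropy depends on cluster degree sums, not the within-cluster spread
        h = random_hypergraph(rng, 10, 14, multisets=True)
        asg = random_assignment(rng, 10, 3)
        base = log_z(h, asg, EntropyModel.DEGREE_CORRECTED)
        # permute vertices within each cluster (relabeling that fixes the
        # partition but shuffles which degree sits where)
        perm = np.arange(10)
        for i in range(3):
            members = np.flatnonzero(asg.c == i)
            perm[members] = members[np.random.default_rng(7).permutation(len(members))]
        edges = [tuple(sorted(perm[v] for v in e)) for e in h.edges]
        h2 = Hypergraph.from_edges(edges, n=10)
        assert log_z(h2, asg, EntropyModel.DEGREE_CORRECTED) == pytest.approx(
            base, abs=1e-9
        )


class TestGraphCount:
    def test_single_within_edge(self):
        h = Hypergraph.from_edges([(0, 1)], n=3)
        asg = Assignment(np.zeros(3, dtype=int), 1)
        mm = module_matrix(h, asg)
        assert log_z_graph(mm, [3]) == pytest.approx(math.log(3))

    def test_empty_graph(self):
        from hypermi import ModuleMatrix

        assert log_z_graph(ModuleMatrix(np.zeros((2, 2), dtype=int)), [3, 4]) == 0.0

    def test_agrees_with_simple_count_on_all_partitions(self, rng):
        # the module-matrix count is the 2-uniform specialization of the
        # simple-hypergraph count; check every labeling of a small graph
        pool = list(combinations(range(6), 2))
        idx = rng.choice(len(pool), size=8, replace=False)
        h = Hypergraph.from_edges([pool[i] for i in idx], n=6)
        for code in range(3**6):
            labels = np.array([(code // 3**v) % 3 for v in range(6)])
            asg = Assignment(labels, 3)
            lhs = log_z_simple(compress(h, asg))
            rhs = log_z_graph(module_matrix(h, asg), asg.cluster_sizes())
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestLogComb:
    def test_branches_agree_at_the_crossover(self):
        # lgamma carries ~N·log N·eps absolute noise, hence the abs tolerance
        n = 10**6 - 3
        direct = sum(math.log(n - j) for j in range(4)) - math.lgamma(5)
        assert log_comb(n, 4) == pytest.approx(direct, abs=1e-8)
        assert log_comb(10**30, 3) == pytest.approx(
            3 * math.log(10**30) - math.log(6), rel=1e-9
        )

    def test_infeasible(self):
        with pytest.raises(ValueError):
            log_comb(3, 5)


class TestIncrementalState:
    @pytest.mark.parametrize(
        "model", ["degree_corrected", "simple", "multiset", "graph"]
    )
    def test_delta_matches_full_recomputation(self, model, rng):
        n, m = 10, 3
        if model == "graph":
            pool = list(combinations(range(n), 2))
            idx = rng.choice(len(pool), size=16, replace=False)
            h = Hypergraph.from_edges([pool[i] for i in idx], n=n)
        elif model == "simple":
            edges = set()
            while len(edges) < 14:
                k = int(rng.integers(2, 4))
                edges.add(tuple(sorted(rng.choice(n, size=k, replace=False))))
            h = Hypergraph.from_edges(sorted(edges), n=n)
        elif model == "multiset":
            h = random_hypergraph(rng, n, 14, sizes=(2, 3))
        else:
            h = random_hypergraph(rng, n, 14, multisets=True)
        state = EntropyState(h, random_assignment(rng, n, m), model)
        for _ in range(250):
            v, b = int(rng.integers(n)), int(rng.integers(m))
            before = state.recompute()
            delta, info = state.delta(v, b)
            if rng.random() < 0.6:
                state.apply(v, b, info)
                after = state.recompute()
                assert delta == pytest.approx(after - before, abs=1e-9)
                assert state.log_z_cached == pytest.approx(after, abs=1e-9)

    def test_self_move_is_zero(self, rng, small_hypergraph):
        asg = random_assignment(rng, 5, 2)
        state = EntropyState(small_hypergraph, asg, "degree_corrected")
        delta, info = state.delta(3, int(asg.c[3]))
        assert delta == 0.0 and info is None

    def test_isolated_vertex_move_free_under_degree_correction(self):
        h = Hypergraph.from_edges([(0, 1)], n=3)  # vertex 2 isolated
        state = EntropyState(h, Assignment(np.array([0, 0, 0]), 2), "degree_corrected")
        delta, info = state.delta(2, 1)
        assert delta == pytest.approx(0.0, abs=1e-12)
        state.apply(2, 1, info)
        assert state.log_z_cached == pytest.approx(state.recompute(), abs=1e-9)

    def test_model_preconditions_enforced(self):
        non_simple = Hypergraph.from_edges([(0, 1), (0, 1)], n=2)
        with pytest.raises(ValueError, match="simple"):
            EntropyState(non_simple, Assignment(np.array([0, 0]), 1), "simple")
        three = Hypergraph.from_edges([(0, 1, 2)], n=3)
        with pytest.raises(ValueError, match="2-uniform"):
            EntropyState(three, Assignment(np.zeros(3, dtype=int), 1), "graph")
        multiset_edge = Hypergraph.from_edges([(0, 0, 1)], n=2)
        with pytest.raises(ValueError, match="repeated"):
            EntropyState(multiset_edge, Assignment(np.array([0, 0]), 1), "multiset")
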