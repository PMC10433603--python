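"""Node scoring, binomial stopping test, BFS traversal and path statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsift.errors import ParameterError
from strainsift.kmer import KmerCountTable
from strainsift.search import (
    assign_counts,
    bfs_search,
    binomial_stop_test,
    leaf_statistics,
    NodeScore,
    resolve_path,
    score_node,
    search_clusters,
)
from strainsift.tree import CST, CSTNode


class TestScoreNode:
    def test_half_matched(self):
        s = score_node(np.array([0, 0, 5, 7]))
        assert (s.frac, s.abund) == (0.5, 6.0)

    def test_fraction_floor_zeroes_abundance(self):
        s = score_node(np.array([1] + [0] * 10))  # frac 1/11 < 0.1
        assert s.abund == 0.0

    def test_floor_boundary_is_inclusive(self):
        s = score_node(np.array([5] + [0] * 9))  # frac exactly 0.1
        assert s.abund == 5.0
        s2 = score_node(np.array([5] + [0] * 10))  # just below
        assert s2.abund == 0.0

    def test_all_zero_and_empty(self):
        assert score_node(np.zeros(4)) == NodeScore(0.0, 0.0)
        assert score_node(np.zeros(0)) == NodeScore(0.0, 0.0)


def exact_binomial_cdf(x: int, n: int, p: Fraction) -> Fraction:
    """Exact rational CDF oracle for X ~ Binomial(n, p)."""
    if x < 0:
        return Fraction(0)
    total = Fraction(0)
    for i in range(min(x, n) + 1):
        total += comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


class TestBinomialStop:
    def test_equal_abundance_traverses(self):
        # P(X <= 0) = e^20·ln(0.01) scale: vanishingly small
        assert binomial_stop_test(20, 20) is True

    def test_large_drop_stops(self):
        # p = 1 - 0.99^20 ≈ 0.182 > 0.05
        assert binomial_stop_test(20, 1) is False

    def test_child_above_parent_traverses(self):
        assert binomial_stop_test(10, 12) is True

    def test_rounding_half_up(self):
        # 19.5 rounds to 20, 19.4 to 19
        assert binomial_stop_test(19.5, 19.5) == binomial_stop_test(20, 20)

    @pytest.mark.parametrize("e,beta", [(0.0, 0.05), (1.0, 0.05), (0.01, 0.0), (0.01, 1.5)])
    def test_parameter_validation(self, e, beta):
        with pytest.raises(ParameterError):
            binomial_stop_test(10, 5, e=e, beta=beta)

    @given(ap=st.integers(0, 120), av=st.integers(0, 120))
    @settings(max_examples=60)
    def test_decision_matches_exact_cdf_oracle(self, ap, av):
        e = Fraction(1, 100)
        p_exact = exact_binomial_cdf(ap - av, ap, 1 - e)
        assert binomial_stop_test(ap, av) is (p_exact < Fraction(5, 100))


def toy_cst(node_kmers: dict[int, list[int]], topology: dict[int, list[int]],
            clusters: dict[int, str]) -> CST:
    """Build an explicit CST from node id -> k-mers / children / cluster."""
    nodes = {i: CSTNode(node_id=i, depth=0, kmers=set(ks)) for i, ks in node_kmers.items()}
    for i, ch in topology.items():
        nodes[i].children = [nodes[c] for c in ch]
        for c in ch:
            nodes[c].parent = nodes[i]
    for i, cid in clusters.items():
        nodes[i].cluster_id = cid

    def set_depth(n, d):
        n.depth = d
        for c in n.children:
            set_depth(c, d + 1)

    root = next(n for n in nodes.values() if n.parent is None)
    set_depth(root, 0)
    return CST(root=root, nodes=[nodes[i] for i in sorted(nodes)])


@pytest.fixture
def four_leaf_cst():
    # root 0 -> (1, 2); 1 -> (3, 4); 2 -> (5, 6); leaves 3..6 = clusters A..D
    node_kmers = {0: list(range(0, 10)), 1: list(range(10, 20)), 2: list(range(20, 30)),
                  3: list(range(30, 40)), 4: list(range(40, 50)),
                  5: list(range(50, 60)), 6: list(range(60, 70))}
    topo = {0: [1, 2], 1: [3, 4], 2: [5, 6]}
    return toy_cst(node_kmers, topo, {3: "A", 4: "B", 5: "C", 6: "D"})


def counts_for(cst: CST, per_node: dict[int, int]) -> KmerCountTable:
    keys, vals = [], []
    for node in cst.nodes:
        c = per_node.get(node.node_id, 0)
        if c:
            for x in node.kmers:
                keys.append(x)
                vals.append(c)
    order = np.argsort(keys)
    return KmerCountTable(
        k=31,
        keys=np.array(keys, dtype=np.uint64)[order] if keys else np.empty(0, np.uint64),
        counts=np.array(vals, dtype=np.int64)[order] if keys else np.empty(0, np.int64),
    )


class TestBFS:
    def test_single_saturated_branch(self, four_leaf_cst):
        counts = counts_for(four_leaf_cst, {0: 10, 1: 10, 3: 10})
        nc = assign_counts(counts, four_leaf_cst)
        scores = {i: score_node(v) for i, v in nc.items()}
        assert bfs_search(four_leaf_cst, scores) == [3]

    def test_zero_counts_no_candidates(self, four_leaf_cst):
        nc = assign_counts(counts_for(four_leaf_cst, {}), four_leaf_cst)
        scores = {i: score_node(v) for i, v in nc.items()}
        assert bfs_search(four_leaf_cst, scores) == []

    def test_two_siblings_both_traversed(self, four_leaf_cst):
        counts = counts_for(four_leaf_cst, {0: 20, 1: 12, 2: 8, 3: 12, 6: 8})
        nc = assign_counts(counts, four_leaf_cst)
        scores = {i: score_node(v) for i, v in nc.items()}
        assert bfs_search(four_leaf_cst, scores) == [3, 6]


class TestResolvePath:
    def test_single_candidate_full_root_path(self, four_leaf_cst):
        assert resolve_path(four_leaf_cst, 3, [3]) == [0, 1, 3]

    def test_sibling_candidates_confined(self, four_leaf_cst):
        # with leaves 3 and 4 identified, each path is just the leaf itself
        assert resolve_path(four_leaf_cst, 3, [3, 4]) == [3]
        # leaf 6 with candidate 3 elsewhere keeps its private subtree (node 2)
        assert resolve_path(four_leaf_cst, 6, [3, 6]) == [2, 6]

    @given(st.integers(0, 3000))
    @settings(max_examples=40)
    def test_matches_maximal_subtree_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # 5-leaf caterpillar: ids 0..8, leaves 4..8
        topo = {0: [1, 4], 1: [2, 5], 2: [3, 6], 3: [7, 8]}
        kmers = {i: [i] for i in range(9)}
        clusters = {i: f"L{i}" for i in (4, 5, 6, 7, 8)}
        cst = toy_cst(kmers, topo, clusters)
        leaves = [4, 5, 6, 7, 8]
        n_cand = int(rng.integers(1, 4))
        cands = sorted(rng.choice(leaves, size=n_cand, replace=False).tolist())
        for v in cands:
            got = resolve_path(cst, v, cands)
            # oracle: deepest-to-root walk, keep extending while subtree clean
            best = [v]
            node = cst.nodes[v]
            while node.parent is not None:
                sub = {l.node_id for l in node.parent.subtree_leaves()}
                if sub & (set(cands) - {v}):
                    break
                node = node.parent
                best.insert(0, node.node_id)
            assert got == best


class TestLeafStatistics:
    def test_weighted_arithmetic(self, four_leaf_cst):
        # node 1: 8/10 positive at 10; leaf 3: 2/10 positive at 5
        counts_keys, counts_vals = [], []
        for x in sorted(four_leaf_cst.nodes[1].kmers)[:8]:
            counts_keys.append(x)
            counts_vals.append(10)
        for x in sorted(four_leaf_cst.nodes[3].kmers)[:2]:
            counts_keys.append(x)
            counts_vals.append(5)
        order = np.argsort(counts_keys)
        table = KmerCountTable(
            k=31,
            keys=np.array(counts_keys, np.uint64)[order],
            counts=np.array(counts_vals, np.int64)[order],
        )
        nc = assign_counts(table, four_leaf_cst)
        hit = leaf_statistics(four_leaf_cst, [1, 3], nc, [])
        assert hit is not None
        assert hit.F == pytest.approx(10 / 20)
        assert hit.A == pytest.approx((8 * 10 + 2 * 5) / 10)  # 9.0

    def test_cutoff_rejects(self, four_leaf_cst):
        counts = counts_for(four_leaf_cst, {3: 5})
        nc = assign_counts(counts, four_leaf_cst)
        # only the leaf matched: F over [0,1,3] = 10/30 < 0.4
        assert leaf_statistics(four_leaf_cst, [0, 1, 3], nc, []) is None

    def test_adjustment_subtracts_other_cluster(self, four_leaf_cst):
        counts = counts_for(four_leaf_cst, {0: 10, 1: 10, 3: 10})
        nc = assign_counts(counts, four_leaf_cst)
        # pretend all of node 1's k-mers also occur in an identified cluster
        other = np.array(sorted(four_leaf_cst.nodes[1].kmers), dtype=np.uint64)
        unadj = leaf_statistics(four_leaf_cst, [1, 3], nc, [])
        adj = leaf_statistics(four_leaf_cst, [1, 3], nc, [(10.0, other)])
        assert unadj.A == pytest.approx(10.0)
        assert adj.F == pytest.approx(0.5)  # node 1 counts floored to 0
        assert adj.A == pytest.approx(10.0)  # leaf evidence only

    def test_empty_path_rejected_with_warning(self, four_leaf_cst, caplog):
        nc = assign_counts(counts_for(four_leaf_cst, {}), four_leaf_cst)
        with caplog.at_level("WARNING"):
            assert leaf_statistics(four_leaf_cst, [0, 1, 3], nc, []) is None


class TestSearchClusters:
    def _arrays(self, cst):
        return {n.cluster_id: np.empty(0, np.uint64) for n in cst.leaves}

    def test_end_to_end_single_cluster(self, four_leaf_cst):
        counts = counts_for(four_leaf_cst, {0: 10, 1: 10, 3: 10})
        hits = search_clusters(four_leaf_cst, counts, self._arrays(four_leaf_cst))
        assert [h.cluster_id for h in hits] == ["A"]
        assert hits[0].path_nodes == [0, 1, 3]

    def test_monotone_under_count_scaling(self, four_leaf_cst):
        base = {0: 12, 1: 12, 3: 12}
        for scale in (1, 3, 10):
            counts = counts_for(four_leaf_cst, {k: v * scale for k, v in base.items()})
            hits = search_clusters(four_leaf_cst, counts, self._arrays(four_leaf_cst))
            assert [h.cluster_id for h in hits] == ["A"]

    def test_ties_ordered_by_abundance_then_id(self, four_leaf_cst):
        counts = counts_for(four_leaf_cst, {0: 20, 1: 12, 2: 8, 3: 12, 6: 8})
        hits = search_clusters(four_leaf_cst, counts, self._arrays(four_leaf_cst))
        assert [h.cluster_id for h in hits] == ["A", "D"]
        assert hits[0].A >= hits[1].A
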