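"""Cluster search: map read k-mer counts onto the CST and BFS with a
binomial stopping test.

Each node ``v`` gets a count vector ``C_v`` (one entry per assigned k-mer).
Two scores drive the search: ``frac_v``, the fraction of the node's k-mers
observed at all, and ``abund_v``, the mean count over observed k-mers
(forced to 0 when frac_v < 0.1, since sparse scattered matches are noise).
A child is traversed only when its abundance cannot be explained by
sequencing errors eroding the parent's abundance: with error rate ``e``,
P[X <= abund_p' − abund_v'] for X ~ Binomial(abund_p', 1−e) must fall below
``beta``.  Accepted leaves are scored over their private root-to-leaf path
(the path inside the maximal subtree containing no other accepted leaf),
with counts of k-mers shared with other identified clusters discounted by
those clusters' abundance estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .errors import ParameterError
from .kmer import KmerCountTable
from .tree import CST, CSTNode

logger = logging.getLogger(__name__)


@dataclass
class NodeScore:
    frac: float
    abund: float


@dataclass
class ClusterHit:
    cluster_id: str
    F: float  # weighted matched fraction over the path
    A: float  # weighted mean match count (cluster abundance estimate)
    path_nodes: list[int] = field(default_factory=list)


NodeCounts = dict[int, np.ndarray]


def assign_counts(counts: KmerCountTable, cst: CST) -> NodeCounts:
    """Per-node count vectors in each node's sorted k-mer order."""
    out: NodeCounts = {}
    for node in cst.nodes:
        arr = node.sorted_kmers()
        out[node.node_id] = counts.lookup(arr) if arr.size else np.zeros(0, np.int64)
    return out


def score_node(C: np.ndarray, frac_floor: float = 0.1) -> NodeScore:
    """frac = |C+|/|C|; abund = mean of positive counts, zeroed below the floor."""
    C = np.asarray(C)
    if C.size == 0:
        logger.warning("scoring an empty (weak, unaugmented) node: score (0, 0)")
        return NodeScore(0.0, 0.0)
    pos = C[C > 0]
    frac = pos.size / C.size
    abund = float(pos.mean()) if pos.size and frac >= frac_floor else 0.0
    return NodeScore(float(frac), abund)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def binomial_stop_pvalue(
    abund_parent: float, abund_child: float, e: float = 0.01
) -> float:
    """P[X <= abund_p' − abund_v'] for X ~ Binomial(abund_p', 1−e), with both
    abundances rounded half-up to integers; 0 when the child exceeds the
    parent (the child cannot be explained as the parent's erosion)."""
    if not (0.0 < e < 1.0):
        raise ParameterError("e must lie in (0, 1)")
    if abund_parent < 0 or abund_child < 0:
        raise ParameterError("abundances must be non-negative")
    ap = _round_half_up(abund_parent)
    av = _round_half_up(abund_child)
    diff = ap - av
    if diff < 0:
        return 0.0  # P(X <= negative) = 0
    return float(binom.cdf(diff, ap, 1.0 - e))


def binomial_stop_test(
    abund_parent: float, abund_child: float, e: float = 0.01, beta: float = 0.05
) -> bool:
    """True (traverse) when the child's abundance is too high to be the
    parent's abundance eroded by sequencing errors."""
    if not (0.0 < beta < 1.0):
        raise ParameterError("beta must lie in (0, 1)")
    return binomial_stop_pvalue(abund_parent, abund_child, e) < beta


def bfs_search(
    cst: CST,
    scores: dict[int, NodeScore],
    e: float = 0.01,
    beta: float = 0.05,
) -> list[int]:
    """Breadth-first traversal from the root; returns candidate leaf node ids."""
    root = cst.root
    if scores[root.node_id].abund <= 0:
        return []
    if root.is_leaf:
        return [root.node_id]
    candidates: list[int] = []
    queue: list[CSTNode] = list(root.children)
    while queue:
        node = queue.pop(0)
        parent = node.parent
        assert parent is not None
        if binomial_stop_test(
            scores[parent.node_id].abund, scores[node.node_id].abund, e, beta
        ):
            if node.is_leaf:
                candidates.append(node.node_id)
            else:
                queue.extend(node.children)
    return candidates


def resolve_path(cst: CST, leaf_id: int, candidate_ids: list[int]) -> list[int]:
    """Nodes from the root of the maximal subtree containing only this
    candidate, down to the leaf (the leaf's private evidence path)."""
    if leaf_id not in candidate_ids:
        raise ParameterError("leaf must be among the candidates")
    others = set(candidate_ids) - {leaf_id}
    node = cst.nodes[leaf_id]
    top = node
    probe = node.parent
    while probe is not None:
        subtree = {l.node_id for l in probe.subtree_leaves()}
        if subtree & others:
            break
        top = probe
        probe = probe.parent
    path: list[int] = []
    cur: CSTNode | None = cst.nodes[leaf_id]
    while cur is not None:
        path.append(cur.node_id)
        if cur.node_id == top.node_id:
            break
        cur = cur.parent
    return list(reversed(path))


def leaf_statistics(
    cst: CST,
    path_nodes: list[int],
    node_counts: NodeCounts,
    other_hits: list[tuple[float, np.ndarray]],
    F_cutoff: float = 0.4,
    frac_floor: float = 0.1,
) -> ClusterHit | None:
    """Weighted path statistics F (matched fraction) and A (match count).

    ``other_hits`` carries (abundance estimate, sorted k-mer array of the
    other identified cluster's strains); counts of path k-mers present in
    such a cluster are reduced by its abundance estimate (floored at 0)
    before scoring, so shared ancestral k-mers are not double-counted.
    """
    leaf = cst.nodes[path_nodes[-1]]
    sum_pos = 0
    sum_len = 0
    weighted = 0.0
    for nid in path_nodes:
        node = cst.nodes[nid]
        arr = node.sorted_kmers()
        C = node_counts[nid].astype(float).copy()
        for a_other, other_keys in other_hits:
            if other_keys.size == 0 or arr.size == 0:
                continue
            idx = np.searchsorted(other_keys, arr)
            idx_c = np.clip(idx, 0, other_keys.size - 1)
            shared = other_keys[idx_c] == arr
            if shared.any():
                C[shared] = np.maximum(0.0, C[shared] - a_other)
        score = score_node(C, frac_floor)
        n_pos = int((C > 0).sum())
        sum_pos += n_pos
        sum_len += C.size
        weighted += n_pos * score.abund
    if sum_len == 0 or sum_pos == 0:
        logger.warning("empty count vectors along the path of leaf %s", leaf.cluster_id)
        return None
    F = sum_pos / sum_len
    A = weighted / sum_pos
    if F <= F_cutoff:
        return None
    return ClusterHit(cluster_id=leaf.cluster_id or "", F=F, A=A, path_nodes=path_nodes)


def search_clusters(
    cst: CST,
    counts: KmerCountTable,
    cluster_kmer_arrays: dict[str, np.ndarray],
    *,
    e: float = 0.01,
    beta: float = 0.05,
    F_cutoff: float = 0.4,
    frac_floor: float = 0.1,
) -> list[ClusterHit]:
    """End-to-end cluster search: count assignment, BFS, path statistics.

    ``cluster_kmer_arrays`` maps cluster_id to the sorted union of its member
    strains' k-mers, used for the cross-cluster count adjustment.  Hits are
    sorted by abundance estimate descending (ties by cluster id).
    """
    node_counts = assign_counts(counts, cst)
    scores = {nid: score_node(vec, frac_floor) for nid, vec in node_counts.items()}
    candidates = bfs_search(cst, scores, e, beta)
    if not candidates:
        return []
    paths = {nid: resolve_path(cst, nid, candidates) for nid in candidates}
    # preliminary (unadjusted) abundance estimates drive the adjustment
    prelim: dict[int, ClusterHit | None] = {
        nid: leaf_statistics(cst, paths[nid], node_counts, [], F_cutoff=-1.0,
                             frac_floor=frac_floor)
        for nid in candidates
    }
    hits: list[ClusterHit] = []
    for nid in candidates:
        if prelim[nid] is None:
            continue
        others = [
            (prelim[o].A, cluster_kmer_arrays[cst.nodes[o].cluster_id or ""])
            for o in candidates
            if o != nid and prelim[o] is not None
        ]
        hit = leaf_statistics(
            cst, paths[nid], node_counts, others, F_cutoff=F_cutoff,
            frac_floor=frac_floor,
        )
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.A, h.cluster_id))
    return hits
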