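"""Cluster Search Tree (CST) construction.

The CST mirrors the cluster-level dendrogram as a full binary tree, each
leaf a strain cluster.  Every node ``v`` is assigned the k-mers unique to its
rooted subtree: starting from per-leaf sets (filtered to k-mers present in at
least ``alpha``% of the cluster's strains), shared k-mers of sibling nodes
are recursively promoted to their parent, and any k-mer that still occurs in
more than one node is removed.  The result, per node, equals

    (intersection of leaf sets under v) − (union of leaf sets outside v).

Nodes left with few k-mers match reads by chance; they are augmented with
extra k-mers that occur in at least one strain of the subtree and in no
strain outside it, preferring high within-subtree prevalence, so the search
gains power without gaining ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cluster import ClusterAssignment, DendroNode
from .errors import InputError, ParameterError
from .kmer import KmerSet

logger = logging.getLogger(__name__)


@dataclass
class LeafKmerSet:
    """Initial k-mer set of one cluster leaf after the prevalence filter."""

    cluster_id: str
    kmers: set[int]
    n_strains: int


@dataclass
class CSTNode:
    node_id: int
    depth: int
    parent: "CSTNode | None" = None
    children: list["CSTNode"] = field(default_factory=list)
    cluster_id: str | None = None  # leaves only
    members: list[str] = field(default_factory=list)
    kmers: set[int] = field(default_factory=set)
    augmented: set[int] = field(default_factory=set)
    _sorted: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def sorted_kmers(self) -> np.ndarray:
        if self._sorted is None or self._sorted.size != len(self.kmers):
            self._sorted = np.fromiter(
                sorted(self.kmers), dtype=np.uint64, count=len(self.kmers)
            )
        return self._sorted

    def subtree_leaves(self) -> list["CSTNode"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.subtree_leaves()]


@dataclass
class CST:
    root: CSTNode
    nodes: list[CSTNode]  # BFS order; node_id == position

    @property
    def leaves(self) -> list[CSTNode]:
        return [n for n in self.nodes if n.is_leaf]

    def leaf_by_cluster(self, cluster_id: str) -> CSTNode:
        for n in self.leaves:
            if n.cluster_id == cluster_id:
                return n
        raise KeyError(cluster_id)


def build_leaf_sets(
    clusters: ClusterAssignment,
    genome_kmers: dict[str, KmerSet],
    alpha: float = 90.0,
) -> dict[str, LeafKmerSet]:
    """Per-cluster k-mer sets keeping k-mers present in >= alpha% of members.

    Single-strain clusters keep the strain's full k-mer set.
    """
    if not (0.0 < alpha <= 100.0):
        raise ParameterError(f"alpha must be in (0, 100], got {alpha}")
    out: dict[str, LeafKmerSet] = {}
    for cid, members in clusters.clusters.items():
        if not members:
            raise InputError(f"cluster {cid} is empty")
        missing = [g for g in members if g not in genome_kmers]
        if missing:
            raise InputError(f"cluster {cid}: missing genomes {missing}")
        if len(members) == 1:
            kept = set(genome_kmers[members[0]].kmers)
        else:
            counts: dict[int, int] = {}
            for g in members:
                for x in genome_kmers[g].kmers:
                    counts[x] = counts.get(x, 0) + 1
            need = alpha / 100.0 * len(members)
            kept = {x for x, c in counts.items() if c >= need - 1e-9}
        out[cid] = LeafKmerSet(cluster_id=cid, kmers=kept, n_strains=len(members))
    return out


def _mirror(dnode: DendroNode, parent: CSTNode | None, depth: int, acc: list) -> CSTNode:
    node = CSTNode(node_id=-1, depth=depth, parent=parent, cluster_id=dnode.genome_id)
    acc.append(node)
    for child in dnode.children:
        node.children.append(_mirror(child, node, depth + 1, acc))
    return node


def build_cst(
    cluster_tree: DendroNode,
    leaf_sets: dict[str, LeafKmerSet],
    members: dict[str, list[str]] | None = None,
) -> CST:
    """Assign node k-mer sets by recursive promotion then global de-duplication.

    Working bottom-up, the intersection of two siblings' current sets moves
    to their parent and is removed from both; afterwards every k-mer still
    present in more than one node is deleted everywhere, leaving pairwise
    disjoint, subtree-unique node sets.
    """
    acc: list[CSTNode] = []
    root = _mirror(cluster_tree, None, 0, acc)
    tree_clusters = {n.cluster_id for n in acc if n.is_leaf}
    if tree_clusters != set(leaf_sets):
        raise InputError(
            f"dendrogram leaves {sorted(c for c in tree_clusters if c)} do not match "
            f"clusters {sorted(leaf_sets)}"
        )
    # BFS ids for determinism
    order: list[CSTNode] = [root]
    for n in order:
        order.extend(n.children)
    for i, n in enumerate(order):
        n.node_id = i
        if n.is_leaf and members is not None:
            n.members = list(members.get(n.cluster_id or "", []))

    def promote(node: CSTNode) -> set[int]:
        if node.is_leaf:
            node.kmers = set(leaf_sets[node.cluster_id].kmers)  # type: ignore[index]
            return node.kmers
        left, right = (promote(c) for c in node.children)
        shared = left & right
        left -= shared
        right -= shared
        node.kmers = shared
        return node.kmers

    promote(root)

    seen: dict[int, int] = {}
    for n in order:
        for x in n.kmers:
            seen[x] = seen.get(x, 0) + 1
    dupes = {x for x, c in seen.items() if c > 1}
    if dupes:
        for n in order:
            n.kmers -= dupes
    return CST(root=root, nodes=order)


def set_formula_node_kmers(cst: CST, leaf_sets: dict[str, LeafKmerSet]) -> dict[int, set[int]]:
    """Direct set-formula value of each node's k-mer set (oracle form):
    intersection over leaves of the subtree minus union over all other leaves."""
    out: dict[int, set[int]] = {}
    all_leaves = cst.leaves
    for node in cst.nodes:
        inside = {l.cluster_id for l in node.subtree_leaves()}
        inter: set[int] | None = None
        for cid in inside:
            s = leaf_sets[cid].kmers  # type: ignore[index]
            inter = set(s) if inter is None else inter & s
        outside_union: set[int] = set()
        for l in all_leaves:
            if l.cluster_id not in inside:
                outside_union |= leaf_sets[l.cluster_id].kmers  # type: ignore[index]
        out[node.node_id] = (inter or set()) - outside_union
    return out


def augment_weak_nodes(
    cst: CST,
    genome_kmers: dict[str, KmerSet],
    clusters: ClusterAssignment,
    min_kmers: int = 1000,
) -> CST:
    """Top up nodes with fewer than ``min_kmers`` k-mers.

    Added k-mers must (i) occur in at least one strain of the node's subtree,
    (ii) occur in no strain outside the subtree, and (iii) not already be
    assigned to any node.  Candidates are taken in decreasing within-subtree
    prevalence (ties by k-mer value) until the node reaches ``min_kmers`` or
    candidates run out; in the latter case the node stays weak and a warning
    is logged.  Augmented k-mers are tracked per node.
    """
    if min_kmers < 0:
        raise ParameterError("min_kmers must be non-negative")
    assigned: set[int] = set()
    for n in cst.nodes:
        assigned |= n.kmers
    strain_sets = {g: ks.kmers for g, ks in genome_kmers.items()}
    all_strains = set()
    for members in clusters.clusters.values():
        all_strains.update(members)
    for node in cst.nodes:  # BFS order: parents first (deterministic)
        deficit = min_kmers - len(node.kmers)
        if deficit <= 0:
            continue
        inside_strains: list[str] = []
        for leaf in node.subtree_leaves():
            inside_strains.extend(clusters.clusters[leaf.cluster_id])  # type: ignore[index]
        outside = all_strains.difference(inside_strains)
        outside_union: set[int] = set()
        for g in sorted(outside):
            outside_union |= strain_sets[g]
        prevalence: dict[int, int] = {}
        for g in inside_strains:
            for x in strain_sets[g]:
                prevalence[x] = prevalence.get(x, 0) + 1
        eligible = [
            x
            for x in prevalence
            if x not in assigned and x not in outside_union
        ]
        eligible.sort(key=lambda x: (-prevalence[x], x))
        added = eligible[:deficit]
        if added:
            node.kmers.update(added)
            node.augmented.update(added)
            assigned.update(added)
            node._sorted = None
        if len(node.kmers) < min_kmers:
            logger.warning(
                "node %d remains weak: %d k-mers (< %d), no further unambiguous "
                "k-mers available",
                node.node_id,
                len(node.kmers),
                min_kmers,
            )
    return cst
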