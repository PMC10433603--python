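"""Genome clustering on exact k-mer Jaccard similarity.

Three stages used by the indexing pipeline:

* an all-against-all similarity matrix;
* single-linkage agglomeration cut at a similarity height ``H`` (0.95 by
  default) — strains whose pairwise Jaccard chain exceeds ``H`` form one
  cluster, the unit the search tree discriminates;
* complete-linkage dereplication at 0.99 to drop near-identical references,
  keeping per group the member with the highest average similarity to the
  rest.

Cluster boundaries are inclusive: similarity >= H joins a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import InputError, ParameterError
from .kmer import KmerSet, jaccard


@dataclass
class SimilarityMatrix:
    genome_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.genome_ids)
        if self.S.shape != (n, n):
            raise InputError("similarity matrix shape does not match genome ids")
        if not np.allclose(self.S, self.S.T):
            raise InputError("similarity matrix must be symmetric")
        if self.S.min() < 0 or self.S.max() > 1 + 1e-12:
            raise InputError("similarities must lie in [0, 1]")

    def index_of(self, genome_id: str) -> int:
        return self.genome_ids.index(genome_id)


@dataclass
class DendroNode:
    """Node of a strictly binary merge tree; ``height`` is the similarity at
    which the two children merged (leaves carry height 1)."""

    height: float
    genome_id: str | None = None
    children: list["DendroNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.genome_id]  # type: ignore[list-item]
        return [g for c in self.children for g in c.leaves()]

    def to_newick(self) -> str:
        return self._newick(parent_height=1.0) + ";"

    def _newick(self, parent_height: float) -> str:
        # branch length = 1-similarity drop relative to the parent merge
        bl = max(0.0, parent_height - self.height)
        if self.is_leaf:
            return f"{self.genome_id}:{bl:.6f}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{bl:.6f}"


@dataclass
class Dendrogram:
    root: DendroNode
    genome_ids: list[str]

    def to_newick(self) -> str:
        return self.root.to_newick()


@dataclass
class ClusterAssignment:
    """Partition of the genomes at similarity cutoff ``H``.

    ``clusters`` maps cluster_id -> member genome ids; ids are C1, C2, ...
    in order of first appearance of a member in the input genome order.
    """

    clusters: dict[str, list[str]]
    H: float

    def genome_to_cluster(self) -> dict[str, str]:
        return {g: c for c, members in self.clusters.items() for g in members}


def build_similarity_matrix(genomes: list[KmerSet]) -> SimilarityMatrix:
    """Exact pairwise Jaccard similarities; diagonal fixed at 1."""
    if not genomes:
        raise InputError("need at least one genome")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate genome ids: {dupes}")
    ks = {g.k for g in genomes}
    if len(ks) > 1:
        raise ParameterError(f"genomes have mixed k: {sorted(ks)}")
    n = len(genomes)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = jaccard(genomes[i], genomes[j])
    return SimilarityMatrix(genome_ids=ids, S=S)


def _linkage(S: SimilarityMatrix, method: str) -> np.ndarray:
    n = len(S.genome_ids)
    if n == 1:
        return np.empty((0, 4))
    D = np.clip(1.0 - S.S, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return linkage(squareform(D, checks=False), method=method)


def _tree_from_linkage(Z: np.ndarray, genome_ids: list[str]) -> DendroNode:
    nodes: dict[int, DendroNode] = {
        i: DendroNode(height=1.0, genome_id=g) for i, g in enumerate(genome_ids)
    }
    n = len(genome_ids)
    for m, (a, b, dist, _size) in enumerate(Z):
        nodes[n + m] = DendroNode(
            height=1.0 - float(dist), children=[nodes[int(a)], nodes[int(b)]]
        )
    return nodes[n + len(Z) - 1] if len(Z) else nodes[0]


def _cut(root: DendroNode, H: float) -> list[list[str]]:
    """Maximal subtrees whose merge similarity >= H (inclusive boundary)."""
    groups: list[list[str]] = []

    def visit(node: DendroNode) -> None:
        if node.is_leaf or node.height >= H - 1e-12:
            groups.append(node.leaves())
        else:
            for c in node.children:
                visit(c)

    visit(root)
    return groups


def single_linkage_clusters(
    S: SimilarityMatrix, H: float
) -> tuple[Dendrogram, ClusterAssignment]:
    """Single-linkage dendrogram on d = 1 − S, cut at similarity ``H``.

    The resulting clusters equal the connected components of the graph with
    edges wherever similarity >= H.
    """
    if not (0.0 < H <= 1.0):
        raise ParameterError(f"H must be in (0, 1], got {H}")
    Z = _linkage(S, "single")
    root = _tree_from_linkage(Z, S.genome_ids)
    dendro = Dendrogram(root=root, genome_ids=list(S.genome_ids))
    order = {g: i for i, g in enumerate(S.genome_ids)}
    groups = _cut(root, H)
    groups.sort(key=lambda ms: min(order[g] for g in ms))
    clusters = {f"C{i + 1}": sorted(ms) for i, ms in enumerate(groups)}
    return dendro, ClusterAssignment(clusters=clusters, H=H)


def cluster_dendrogram(dendro: Dendrogram, assignment: ClusterAssignment) -> DendroNode:
    """Collapse the genome dendrogram to a strictly binary tree over clusters.

    Each maximal subtree whose leaves are exactly one cluster becomes a leaf
    labelled with that cluster id; the topology above is kept.
    """
    member_to_cluster = assignment.genome_to_cluster()

    def collapse(node: DendroNode) -> DendroNode:
        leaves = node.leaves()
        cids = {member_to_cluster[g] for g in leaves}
        if len(cids) == 1:
            return DendroNode(height=node.height, genome_id=cids.pop())
        return DendroNode(height=node.height, children=[collapse(c) for c in node.children])

    return collapse(dendro.root)


def dereplicate(S: SimilarityMatrix, threshold: float = 0.99) -> list[str]:
    """Representatives after complete-linkage grouping at ``threshold``.

    Within each complete-linkage group (all pairwise similarities >=
    threshold) the member with the highest mean similarity to the other
    members is kept; ties go to the smallest genome id.  Singletons represent
    themselves.  The representative list is sorted by genome id.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    n = len(S.genome_ids)
    if n == 1:
        return list(S.genome_ids)
    Z = _linkage(S, "complete")
    groups = _cut(_tree_from_linkage(Z, S.genome_ids), threshold)
    reps: list[str] = []
    idx = {g: i for i, g in enumerate(S.genome_ids)}
    for members in groups:
        if len(members) == 1:
            reps.append(members[0])
            continue
        rows = [idx[g] for g in members]
        sub = S.S[np.ix_(rows, rows)]
        mean_sim = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        best = sorted(zip(-mean_sim, members))[0][1]
        reps.append(best)
    return sorted(reps)
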