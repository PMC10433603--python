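"""End-to-end workflows: build an index from genomes; profile a read set.

``build_index`` runs dereplication → similarity matrix → single-linkage
clustering → CST construction and augmentation → per-cluster strain
matrices.  ``profile_sample`` counts the index's query k-mers in the reads,
searches the CST for clusters, resolves strains inside each identified
cluster, and merges the per-cluster depths into one relative-abundance
profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cluster import (
    build_similarity_matrix,
    cluster_dendrogram,
    dereplicate,
    single_linkage_clusters,
)
from .config import RunConfig
from .index import Index
from .io import read_fasta
from .kmer import (
    KmerCountTable,
    KmerSet,
    count_kmers_in_fastq,
    count_kmers_in_sequences,
    extract_canonical_kmers,
)
from .resolve import (
    StrainCall,
    build_strain_matrix,
    estimate_depths,
    iterative_strain_detection,
    mask_cross_cluster,
    observation_vector,
    relative_abundance,
    zero_outliers,
)
from .search import ClusterHit, search_clusters
from .tree import augment_weak_nodes, build_cst, build_leaf_sets

logger = logging.getLogger(__name__)


@dataclass
class SampleProfile:
    cluster_hits: list[ClusterHit]
    strain_calls: list[StrainCall]
    diagnostics: dict = field(default_factory=dict)


def load_genomes(
    fasta_paths: Iterable[str | Path], k: int
) -> dict[str, KmerSet]:
    """One KmerSet per FASTA file; the genome id is the file stem."""
    out: dict[str, KmerSet] = {}
    errors = []
    for path in sorted(Path(p) for p in fasta_paths):
        try:
            records = read_fasta(path)
        except Exception as exc:  # collected so the caller sees every bad file
            errors.append(f"{path}: {exc}")
            continue
        out[path.stem] = extract_canonical_kmers(records, k, genome_id=path.stem)
    if errors:
        raise OSError("unreadable FASTA input(s):\n" + "\n".join(errors))
    return out


def build_index(
    genome_kmers: dict[str, KmerSet],
    config: RunConfig | None = None,
) -> Index:
    """Full indexing pipeline over pre-extracted genome k-mer sets."""
    config = (config or RunConfig()).validate()
    S_full = build_similarity_matrix([genome_kmers[g] for g in sorted(genome_kmers)])
    reps = dereplicate(S_full, config.derep_threshold)
    dropped = sorted(set(genome_kmers) - set(reps))
    if dropped:
        logger.warning(
            "dereplication (complete linkage at %.2f) dropped %d near-identical "
            "genomes: %s",
            config.derep_threshold,
            len(dropped),
            ", ".join(dropped),
        )
    kept = {g: genome_kmers[g] for g in reps}
    S = build_similarity_matrix([kept[g] for g in sorted(kept)])
    dendro, assignment = single_linkage_clusters(S, config.H)
    leaf_sets = build_leaf_sets(assignment, kept, config.alpha)
    ctree = cluster_dendrogram(dendro, assignment)
    cst = build_cst(ctree, leaf_sets, members=assignment.clusters)
    cst = augment_weak_nodes(cst, kept, assignment, config.min_kmers)
    matrices = {}
    cluster_kmers = {}
    for cid, members in assignment.clusters.items():
        matrices[cid] = build_strain_matrix(
            cid,
            [kept[g] for g in members],
            single_strain_cap=config.single_strain_cap,
            annotate=config.annotate_patterns,
        )
        union: set[int] = set()
        for g in members:
            union |= kept[g].kmers
        cluster_kmers[cid] = np.fromiter(sorted(union), dtype=np.uint64, count=len(union))
    manifest = [
        (g, cid, len(kept[g].kmers))
        for cid, members in assignment.clusters.items()
        for g in members
    ]
    logger.info(
        "index: %d genomes in %d clusters (sizes %s); %d CST nodes",
        len(kept),
        len(assignment.clusters),
        sorted((len(m) for m in assignment.clusters.values()), reverse=True),
        len(cst.nodes),
    )
    return Index(
        config=config,
        cst=cst,
        manifest=manifest,
        matrices=matrices,
        cluster_kmers=cluster_kmers,
    )


def build_index_from_fastas(
    fasta_paths: Iterable[str | Path], config: RunConfig | None = None
) -> Index:
    config = (config or RunConfig()).validate()
    return build_index(load_genomes(fasta_paths, config.k), config)


def count_sample(
    index: Index,
    fastq_paths: Sequence[str | Path] | None = None,
    sequences: Iterable[str] | None = None,
) -> KmerCountTable:
    query = index.query_kmers()
    if fastq_paths is not None:
        return count_kmers_in_fastq([str(p) for p in fastq_paths], query, index.config.k)
    if sequences is None:
        raise ValueError("either fastq_paths or sequences is required")
    return count_kmers_in_sequences(sequences, query, index.config.k)


def profile_counts(index: Index, counts: KmerCountTable) -> SampleProfile:
    """Cluster search + strain resolution from a precomputed count table."""
    cfg = index.config
    hits = search_clusters(
        index.cst,
        counts,
        index.cluster_kmers,
        e=cfg.e,
        beta=cfg.beta,
        F_cutoff=cfg.F_cutoff,
        frac_floor=cfg.frac_floor,
    )
    diagnostics: dict = {"cluster_hits": [vars(h).copy() for h in hits]}
    if not hits:
        return SampleProfile(cluster_hits=[], strain_calls=[], diagnostics=diagnostics)
    per_cluster: dict[str, tuple[list[str], np.ndarray]] = {}
    cluster_A = {h.cluster_id: h.A for h in hits}
    for hit in hits:
        matrix = index.matrices[hit.cluster_id]
        y = observation_vector(matrix, counts)
        others = [
            index.cluster_kmers[h.cluster_id] for h in hits if h.cluster_id != hit.cluster_id
        ]
        y = mask_cross_cluster(y, matrix, others)
        selected = iterative_strain_detection(matrix, y, cfg.stop_kmers)
        diagnostics.setdefault("selection", {})[hit.cluster_id] = list(selected)
        if not selected:
            continue
        cols = [matrix.strain_ids.index(s) for s in selected]
        # regression sees the masked but untrimmed counts: the percentile trim
        # is a detection-stage guard and would clip true high-coverage rows
        beta = estimate_depths(
            matrix.X[:, cols].astype(float),
            y,
            strain_ids=selected,
        )
        per_cluster[hit.cluster_id] = (list(selected), beta)
    calls = relative_abundance(per_cluster, cluster_A) if per_cluster else []
    diagnostics["depths"] = {
        cid: dict(zip(sids, map(float, beta))) for cid, (sids, beta) in per_cluster.items()
    }
    return SampleProfile(cluster_hits=hits, strain_calls=calls, diagnostics=diagnostics)


def profile_sample(
    index: Index,
    fastq_paths: Sequence[str | Path] | None = None,
    sequences: Iterable[str] | None = None,
) -> SampleProfile:
    return profile_counts(index, count_sample(index, fastq_paths, sequences))
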