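"""Shared fixtures: a session-scoped synthetic species and its index."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from strainsift.config import RunConfig
from strainsift.kmer import extract_canonical_kmers
from strainsift.pipeline import build_index
from strainsift.sim import StrainSimConfig, generate_strain_set

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

SPECIES_SEED = 1


@pytest.fixture(scope="session")
def species():
    """Synthetic 20-strain, 6-cluster species (default generator conditions)."""
    seqs, manifest = generate_strain_set(StrainSimConfig(seed=SPECIES_SEED))
    return seqs, manifest


@pytest.fixture(scope="session")
def genome_kmers(species):
    seqs, _ = species
    return {
        sid: extract_canonical_kmers([(sid, seq)], 31, genome_id=sid)
        for sid, seq in seqs.items()
    }


@pytest.fixture(scope="session")
def index(genome_kmers):
    return build_index(genome_kmers, RunConfig())


@pytest.fixture(scope="session")
def true_clusters(species, index):
    """Map each strain to its index cluster id, with the truth manifest's
    grouping verified to coincide."""
    _, manifest = species
    by_index = {g: c for c, ms in index.cluster_members().items() for g in ms}
    truth_groups = manifest.groupby("cluster_id").strain_id.apply(frozenset)
    index_groups = {frozenset(ms) for ms in index.cluster_members().values()}
    assert set(truth_groups) == index_groups, "clustering does not match simulation truth"
    return by_index


def flat_reads(pairs):
    """Flatten paired reads into a sequence list."""
    out = []
    for p in pairs:
        if isinstance(p, tuple):
            out.extend(p)
        else:
            out.append(p)
    return out
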