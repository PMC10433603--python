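"""Canonical k-mer primitives.

A k-mer key is the lexicographically smaller of a k-length ACGT word and its
reverse complement, stored as a 2-bit-per-base integer (A=0, C=1, G=2, T=3;
the numeric order of encodings equals lexicographic order of the words, so
``min`` on integers is ``min`` on strings).  Odd k is required so no k-mer is
its own reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ParameterError
from .io import iter_fastq_sequences

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")


def check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or k % 2 == 0 or not (1 <= k <= 63):
        raise ParameterError(f"k must be an odd integer in [1, 63], got {k!r}")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved per base map)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmer(kmer: str) -> int:
    """2-bit encode an ACGT word (most significant base first)."""
    val = 0
    for ch in kmer:
        code = int(_BASE_CODE[ord(ch)])
        if code > 3:
            raise ParameterError(f"non-ACGT base {ch!r} in k-mer")
        val = (val << 2) | code
    return val


def decode_kmer(val: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_BASES[(val >> shift) & 3])
    return "".join(out)


def revcomp_int(val: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (val & 3))
        val >>= 2
    return rc


def canonical_int(val: int, k: int) -> int:
    return min(val, revcomp_int(val, k))


def canonical_kmer(kmer: str) -> str:
    """Canonical form of a k-mer string (min of itself and its revcomp)."""
    return min(kmer.upper(), revcomp(kmer.upper()))


def canonical_kmer_array(seq: str, k: int) -> np.ndarray:
    """All canonical k-mers of ``seq`` as a uint64 array (duplicates kept).

    Windows containing any non-ACGT character are skipped.
    """
    check_k(k)
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        win = c64[j : j + m]
        fwd = (fwd << np.uint64(2)) + win
        rc = rc + ((three - win) << np.uint64(2 * j))
    bad = np.concatenate(([0], np.cumsum(codes > 3)))
    valid = (bad[k:] - bad[:-k]) == 0
    return np.minimum(fwd, rc)[valid]


@dataclass
class KmerSet:
    """Canonical k-mer content of one genome (or one tree node)."""

    genome_id: str
    k: int
    kmers: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.kmers)

    def sorted_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.kmers), dtype=np.uint64, count=len(self.kmers))


@dataclass
class KmerCountTable:
    """Occurrence counts for a fixed query set of canonical k-mers.

    ``keys`` is sorted; ``counts`` is aligned to it.  K-mers observed in the
    reads but absent from the query are never stored.
    """

    k: int
    keys: np.ndarray
    counts: np.ndarray

    def get(self, kmer: int, default: int = 0) -> int:
        i = int(np.searchsorted(self.keys, np.uint64(kmer)))
        if i < self.keys.size and self.keys[i] == np.uint64(kmer):
            return int(self.counts[i])
        return default

    def lookup(self, kmers: np.ndarray) -> np.ndarray:
        """Counts for an arbitrary uint64 key array (0 for unknown keys)."""
        kmers = np.asarray(kmers, dtype=np.uint64)
        idx = np.searchsorted(self.keys, kmers)
        idx_c = np.clip(idx, 0, max(self.keys.size - 1, 0))
        out = np.zeros(kmers.size, dtype=np.int64)
        if self.keys.size:
            hit = self.keys[idx_c] == kmers
            out[hit] = self.counts[idx_c[hit]]
        return out

    def to_dict(self) -> dict[int, int]:
        return {int(x): int(c) for x, c in zip(self.keys, self.counts)}


def extract_canonical_kmers(
    records: Iterable[tuple[str, str]], k: int, genome_id: str | None = None
) -> KmerSet:
    """Union of canonical k-mers over all records/contigs of one genome."""
    check_k(k)
    kmers: set[int] = set()
    name = genome_id
    n_records = 0
    for rec_id, seq in records:
        n_records += 1
        if name is None:
            name = rec_id
        arr = canonical_kmer_array(seq, k)
        if arr.size:
            kmers.update(np.unique(arr).tolist())
    if n_records == 0:
        raise FormatError("no sequence records in input")
    return KmerSet(genome_id=name or "", k=k, kmers=kmers)


def count_kmers_in_reads(
    fastq_paths: Sequence[str] | Iterable[str],
    query: set[int] | np.ndarray,
    k: int,
    *,
    batch_bases: int = 4_000_000,
) -> KmerCountTable:
    """Count occurrences of the query k-mers (canonically) across FASTQ reads.

    Alias of :func:`count_kmers_in_fastq`; library callers holding in-memory
    sequences use :func:`count_kmers_in_sequences`.
    """
    return count_kmers_in_fastq(list(fastq_paths), query, k, batch_bases=batch_bases)


def _query_keys(query: set[int] | np.ndarray) -> np.ndarray:
    if isinstance(query, np.ndarray):
        keys = np.asarray(query, dtype=np.uint64)
        keys = np.unique(keys)
    else:
        keys = np.fromiter(sorted(query), dtype=np.uint64, count=len(query))
    if keys.size == 0:
        raise ParameterError("query k-mer set must be non-empty")
    return keys


def count_kmers_in_sequences(
    sequences: Iterable[str],
    query: set[int] | np.ndarray,
    k: int,
    *,
    batch_bases: int = 4_000_000,
) -> KmerCountTable:
    """As :func:`count_kmers_in_reads` but over in-memory sequences."""
    check_k(k)
    keys = _query_keys(query)
    counts = np.zeros(keys.size, dtype=np.int64)
    chunk: list[str] = []
    size = 0

    def flush() -> None:
        nonlocal chunk, size
        if not chunk:
            return
        # 'N' separators prevent windows spanning two reads
        arr = canonical_kmer_array(("N" * k).join(chunk), k)
        if arr.size:
            idx = np.searchsorted(keys, arr)
            idx_c = np.clip(idx, 0, keys.size - 1)
            hit = keys[idx_c] == arr
            np.add.at(counts, idx_c[hit], 1)
        chunk, size = [], 0

    for seq in sequences:
        chunk.append(seq)
        size += len(seq)
        if size >= batch_bases:
            flush()
    flush()
    return KmerCountTable(k=k, keys=keys, counts=counts)


def count_kmers_in_fastq(
    fastq_paths: Sequence[str],
    query: set[int] | np.ndarray,
    k: int,
    *,
    batch_bases: int = 4_000_000,
) -> KmerCountTable:
    """Count query k-mers across one or more (optionally gzipped) FASTQ files."""
    def gen():
        for path in fastq_paths:
            yield from iter_fastq_sequences(path)

    return count_kmers_in_sequences(gen(), query, k, batch_bases=batch_bases)


def jaccard(a: KmerSet, b: KmerSet) -> float:
    """Exact Jaccard similarity |a∩b| / |a∪b| of two k-mer sets."""
    if a.k != b.k:
        raise ParameterError(f"mismatched k: {a.k} vs {b.k}")
    if not a.kmers and not b.kmers:
        raise ParameterError("Jaccard undefined for two empty k-mer sets")
    inter = len(a.kmers & b.kmers)
    union = len(a.kmers) + len(b.kmers) - inter
    return inter / union


def mash_distance(j: float, k: int) -> float:
    """Mash distance from a Jaccard similarity: -(1/k)·ln(2j/(1+j)).

    Identical sets give 0; disjoint sets are capped at 1.
    """
    if not (0.0 <= j <= 1.0):
        raise ParameterError(f"Jaccard similarity must be in [0, 1], got {j}")
    check_k(k)
    if j == 1.0:
        return 0.0
    if j == 0.0:
        return 1.0
    return min(1.0, -np.log(2.0 * j / (1.0 + j)) / k)
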