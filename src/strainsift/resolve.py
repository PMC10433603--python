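"""Within-cluster strain resolution.

Once the tree search pins down a cluster, strains inside it are told apart
with every k-mer that has discriminative power: the binary presence matrix X
(M k-mers × N strains) keeps exactly the k-mers whose presence pattern
across the cluster's strains is non-constant.  Rows are annotated by origin:

* ``strain_specific`` — present in exactly one strain (private regions);
* ``joint`` — SNV/indel alternatives in otherwise shared context, detected
  as a Hamming-1 partner k-mer with the complementary presence pattern;
* ``group_specific`` — the rest, typically structural variants shared by a
  subset of strains.

Detection is iterative matrix multiplication: score every strain by
f_j = X[:,j]·y against the observed occurrence vector y, take the best,
zero y at that strain's k-mers, repeat until the number of still-positive
k-mers drops below the stop threshold.  Depths of the selected strains are
then estimated by non-negative elastic-net regression of y on the selected
columns, and abundances merged across clusters using the tree-search
cluster abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNetCV

from .errors import InputError, ParameterError
from .kmer import KmerCountTable, KmerSet, canonical_int, revcomp_int

logger = logging.getLogger(__name__)

STRAIN_SPECIFIC = "strain_specific"
GROUP_SPECIFIC = "group_specific"
JOINT = "joint"


@dataclass
class StrainMatrix:
    cluster_id: str
    k: int
    kmer_keys: np.ndarray  # sorted uint64, length M
    strain_ids: list[str]  # sorted, length N
    X: np.ndarray  # (M, N) uint8
    pattern_class: list[str] = field(default_factory=list)

    @property
    def M(self) -> int:
        return int(self.kmer_keys.size)

    @property
    def N(self) -> int:
        return len(self.strain_ids)


@dataclass
class StrainCall:
    strain_id: str
    cluster_id: str
    rank: int  # selection order within the cluster (1-based)
    depth: float  # elastic-net coefficient, per-k-mer coverage units
    within_cluster_abundance: float
    relative_abundance: float


def _neighbors(kmer: int, k: int) -> list[int]:
    """Canonical keys of all Hamming-1 neighbors of a canonical k-mer."""
    out = []
    for pos in range(k):
        shift = 2 * pos
        cur = (kmer >> shift) & 3
        for b in range(4):
            if b != cur:
                out.append(canonical_int((kmer & ~(3 << shift)) | (b << shift), k))
    return out


def build_strain_matrix(
    cluster_id: str,
    genomes: list[KmerSet],
    *,
    single_strain_cap: int = 20000,
    max_rows_per_pattern: int | None = None,
    annotate: bool = True,
) -> StrainMatrix:
    """Presence matrix over k-mers with non-constant pattern across strains.

    A single-strain cluster yields a degenerate all-ones column over a capped
    sample of the strain's k-mers (sorted order; used only for depth
    estimation).  Strains with identical k-mer content are rejected: their
    columns would be indistinguishable.
    """
    if not genomes:
        raise InputError("empty cluster")
    k = genomes[0].k
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    strain_ids = [g.genome_id for g in genomes]
    if len(genomes) == 1:
        keys = genomes[0].sorted_array()[:single_strain_cap]
        return StrainMatrix(
            cluster_id=cluster_id,
            k=k,
            kmer_keys=keys,
            strain_ids=strain_ids,
            X=np.ones((keys.size, 1), dtype=np.uint8),
            pattern_class=[GROUP_SPECIFIC] * keys.size,
        )
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            if genomes[i].kmers == genomes[j].kmers:
                raise InputError(
                    f"strains {strain_ids[i]} and {strain_ids[j]} have identical "
                    "k-mer content; columns would not be distinct"
                )
    N = len(genomes)
    full = (1 << N) - 1
    pattern: dict[int, int] = {}
    for j, g in enumerate(genomes):
        bit = 1 << j
        for x in g.kmers:
            pattern[x] = pattern.get(x, 0) | bit
    rows = {x: p for x, p in pattern.items() if p != full}
    keys = np.fromiter(sorted(rows), dtype=np.uint64, count=len(rows))
    if max_rows_per_pattern is not None:
        keep_mask = np.ones(keys.size, dtype=bool)
        per_pattern: dict[int, int] = {}
        for i, x in enumerate(keys):
            p = rows[int(x)]
            c = per_pattern.get(p, 0)
            if c >= max_rows_per_pattern:
                keep_mask[i] = False
            else:
                per_pattern[p] = c + 1
        keys = keys[keep_mask]
    X = np.zeros((keys.size, N), dtype=np.uint8)
    pats = np.fromiter((rows[int(x)] for x in keys), dtype=np.int64, count=keys.size)
    for j in range(N):
        X[:, j] = (pats >> j) & 1
    classes: list[str] = []
    if annotate:
        for x, p in zip(keys, pats):
            p = int(p)
            # SNV alternatives outrank the popcount rule: a variant k-mer with
            # a complementary-pattern Hamming-1 partner is joint even if it is
            # carried by a single strain
            if any(pattern.get(nb) == (full ^ p) for nb in _neighbors(int(x), k)):
                classes.append(JOINT)
            elif bin(p).count("1") == 1:
                classes.append(STRAIN_SPECIFIC)
            else:
                classes.append(GROUP_SPECIFIC)
    else:
        classes = [GROUP_SPECIFIC] * keys.size
    return StrainMatrix(
        cluster_id=cluster_id,
        k=k,
        kmer_keys=keys,
        strain_ids=strain_ids,
        X=X,
        pattern_class=classes,
    )


def observation_vector(matrix: StrainMatrix, counts: KmerCountTable) -> np.ndarray:
    """Read occurrences aligned to the matrix's k-mer keys."""
    return counts.lookup(matrix.kmer_keys).astype(float)


def mask_cross_cluster(
    y: np.ndarray,
    matrix: StrainMatrix,
    other_cluster_kmers: list[np.ndarray],
) -> np.ndarray:
    """Zero occurrences of k-mers found in other *identified* clusters."""
    y = np.asarray(y, dtype=float).copy()
    for keys in other_cluster_kmers:
        if keys.size == 0:
            continue
        idx = np.searchsorted(keys, matrix.kmer_keys)
        idx_c = np.clip(idx, 0, keys.size - 1)
        y[keys[idx_c] == matrix.kmer_keys] = 0.0
    return y


def zero_outliers(y: np.ndarray) -> np.ndarray:
    """Zero entries outside the [5th, 95th] percentile of the positive values."""
    y = np.asarray(y, dtype=float).copy()
    pos = y[y > 0]
    if pos.size == 0:
        return y
    # attained-value quantiles so the band is never empty on small vectors
    lo = np.percentile(pos, 5.0, method="lower")
    hi = np.percentile(pos, 95.0, method="higher")
    y[(y > 0) & ((y < lo) | (y > hi))] = 0.0
    return y


def stop_threshold(M: int, stop_kmers: int = 1240) -> int:
    """Count-mode stop level: stop when fewer k-mers than this stay positive.

    Matrices with fewer than 10×1240 rows use a proportional threshold (a
    tenth of the rows).  Only used by the count stop semantics; the default
    occurrence-sum semantics uses ``stop_kmers`` unscaled, since remaining
    true-strain occurrences scale with sequencing depth while error-induced
    occurrences stay near one per k-mer.
    """
    if M >= 10 * stop_kmers:
        return stop_kmers
    return max(1, round(M * stop_kmers / (10 * stop_kmers)))


def iterative_strain_detection(
    matrix: StrainMatrix,
    y: np.ndarray,
    stop_kmers: int = 1240,
    *,
    stop_on: str = "sum",
) -> list[str]:
    """Greedy strain selection by score f_j = X[:,j]·y.

    Outliers in y are zeroed once up front.  Each round selects the highest
    scoring not-yet-selected strain (ties to the smallest strain id) and
    zeroes y at all of that strain's k-mers; iteration ends when the total
    remaining occurrence of positive k-mers (``stop_on='sum'``, default) or
    the number of positive k-mers (``stop_on='count'``, scaled for small
    matrices) drops below the stop threshold, or no strain scores positive.
    """
    if stop_on not in ("sum", "count"):
        raise ParameterError(f"stop_on must be 'sum' or 'count', got {stop_on!r}")
    y = zero_outliers(y)
    stop = stop_kmers if stop_on == "sum" else stop_threshold(matrix.M, stop_kmers)
    remaining = list(range(matrix.N))
    order: list[str] = []
    while remaining:
        level = float(y.sum()) if stop_on == "sum" else int((y > 0).sum())
        if level < stop:
            break
        scores = np.array([float(matrix.X[:, j] @ y) for j in remaining])
        best = int(np.argmax(scores))  # strain_ids sorted: first argmax = smallest id
        if scores[best] <= 0:
            break
        j = remaining.pop(best)
        order.append(matrix.strain_ids[j])
        y = y.copy()
        y[matrix.X[:, j] > 0] = 0.0
    return order


def estimate_depths(
    X_selected: np.ndarray,
    y: np.ndarray,
    *,
    strain_ids: list[str] | None = None,
    l1_ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_alphas: int = 50,
    eps: float = 1e-4,
    cv: int = 5,
    max_iter: int = 10000,
) -> np.ndarray:
    """Non-negative elastic-net depths: argmin_{β>=0} ||y − Xβ||² + penalty.

    The mixing weight and penalty strength are tuned by k-fold
    cross-validation over a log-spaced path of ``n_alphas`` values down to
    ``eps``·λ_max per l1 ratio; no intercept, no standardization (binary
    design, comparable column scales).  Deterministic: contiguous folds,
    cyclic coordinate descent.
    """
    X = np.asarray(X_selected, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ParameterError("design matrix and observation vector disagree")
    M, N = X.shape
    if N < 1 or M < N:
        raise ParameterError(f"need M >= N' >= 1, got M={M}, N'={N}")
    for a in range(N):
        for b in range(a + 1, N):
            if np.array_equal(X[:, a], X[:, b]):
                na = strain_ids[a] if strain_ids else f"column {a}"
                nb = strain_ids[b] if strain_ids else f"column {b}"
                raise InputError(f"degenerate design: {na} and {nb} are identical")
    if not np.any(y):
        return np.zeros(N)
    model = ElasticNetCV(
        l1_ratio=list(l1_ratios),
        alphas=n_alphas,
        eps=eps,
        cv=min(cv, M),
        positive=True,
        fit_intercept=False,
        max_iter=max_iter,
    )
    with np.errstate(all="ignore"):
        model.fit(X, y)
    return np.maximum(model.coef_, 0.0)


def relative_abundance(
    per_cluster: dict[str, tuple[list[str], np.ndarray]],
    cluster_abundance: dict[str, float],
) -> list[StrainCall]:
    """Merge per-cluster depths into one relative-abundance profile.

    Within a cluster, abundances are the normalized depth coefficients;
    across clusters each strain's share is weighted by its cluster's
    tree-search abundance: RA_i = a_i·C_i / Σ_j a_j·C_j.  Strains with zero
    depth are dropped; if every coefficient is zero the profile is empty.
    """
    calls: list[StrainCall] = []
    for cid, (strain_ids, beta) in sorted(per_cluster.items()):
        beta = np.asarray(beta, dtype=float)
        total = float(beta.sum())
        if total <= 0:
            logger.warning("cluster %s: all depth coefficients are zero", cid)
            continue
        C = cluster_abundance[cid]
        for rank, (sid, b) in enumerate(zip(strain_ids, beta), start=1):
            if b <= 0:
                continue
            calls.append(
                StrainCall(
                    strain_id=sid,
                    cluster_id=cid,
                    rank=rank,
                    depth=float(b),
                    within_cluster_abundance=float(b / total),
                    relative_abundance=float(b / total * C),  # normalized below
                )
            )
    if not calls:
        logger.warning("no strain has a positive depth estimate; empty profile")
        return []
    Z = sum(c.relative_abundance for c in calls)
    for c in calls:
        c.relative_abundance = c.relative_abundance / Z
    calls.sort(key=lambda c: (-c.relative_abundance, c.strain_id))
    return calls
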