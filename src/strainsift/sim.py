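"""Seeded synthetic strain sets and short-read simulation.

The genome generator emulates a single bacterial species at desk scale: a
random ancestral genome radiates into cluster ancestors (between-cluster
divergence, well below the clustering cutoff in Jaccard terms), each of
which radiates into strains (within-cluster divergence, above the cutoff),
with per-strain segmental insertions/deletions supplying strain- and
group-specific k-mers.  Generated similarity structure is verified against
the configured Jaccard targets and regenerated with nudged rates a bounded
number of times if it misses them.

The read simulator follows the benchmark protocol of ART-style Illumina
simulation: paired 250 bp reads, fragment length 600±150, uniform
substitution errors at 1%, constant quality strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, StrainSiftError
from .io import write_fasta, write_fastq
from .kmer import extract_canonical_kmers, jaccard, revcomp

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class StrainSimConfig:
    genome_length: int = 50_000
    strains_per_cluster: tuple[int, ...] = (5, 4, 4, 3, 2, 2)
    between_sub_rate: float = 5e-3
    between_indel_rate: float = 1e-4
    within_sub_rate: float = 1.2e-4
    within_indel_rate: float = 2e-5
    indel_length_p: float = 0.1  # geometric; mean length 1/p
    cluster_segment_events: int = 1  # one deletion + one insertion per cluster ancestor
    strain_segment_events: int = 1  # one deletion + one insertion per strain
    segment_length_range: tuple[int, int] = (80, 200)
    seed: int = 0
    k: int = 31  # used only for the post-generation similarity verification
    target_within: float = 0.95
    target_between: float = 0.95
    max_retries: int = 3

    @property
    def n_clusters(self) -> int:
        return len(self.strains_per_cluster)

    @property
    def n_strains(self) -> int:
        return sum(self.strains_per_cluster)


@dataclass
class ReadSimConfig:
    depth: float
    read_length: int = 250
    paired: bool = True
    fragment_mean: float = 600.0
    fragment_sd: float = 150.0
    error_rate: float = 0.01
    seed: int = 0


def _random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    indel_length_p: float,
    n_segment_del: int,
    n_segment_ins: int,
    segment_length_range: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[str, dict[str, int]]:
    """Apply substitutions, small indels and segmental events to a sequence."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    L = arr.size
    n_sub = rng.binomial(L, sub_rate)
    stats = {"n_sub": int(n_sub), "n_indel": 0, "n_segment": 0}
    if n_sub:
        pos = rng.choice(L, size=n_sub, replace=False)
        base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        for p in pos:
            choices = base_codes[base_codes != arr[p]]
            arr[p] = choices[rng.integers(0, 3)]
    s = arr.tobytes().decode("ascii")
    # small indels, applied right-to-left so positions stay valid
    n_indel = rng.binomial(L, indel_rate)
    stats["n_indel"] = int(n_indel)
    if n_indel:
        positions = np.sort(rng.integers(0, len(s), size=n_indel))[::-1]
        for p in positions:
            length = int(rng.geometric(indel_length_p))
            if rng.random() < 0.5:
                s = s[:p] + s[p + length :]
            else:
                ins = "".join(_BASES[rng.integers(0, 4, size=length)])
                s = s[:p] + ins + s[p:]
    lo, hi = segment_length_range
    for _ in range(n_segment_del):
        length = int(rng.integers(lo, hi + 1))
        if len(s) > length + 1:
            p = int(rng.integers(0, len(s) - length))
            s = s[:p] + s[p + length :]
            stats["n_segment"] += 1
    for _ in range(n_segment_ins):
        length = int(rng.integers(lo, hi + 1))
        p = int(rng.integers(0, len(s)))
        ins = "".join(_BASES[rng.integers(0, 4, size=length)])
        s = s[:p] + ins + s[p:]
        stats["n_segment"] += 1
    return s, stats


def _validate_sim_config(config: StrainSimConfig) -> None:
    rates = (
        config.between_sub_rate,
        config.between_indel_rate,
        config.within_sub_rate,
        config.within_indel_rate,
    )
    if any(not (0.0 <= r < 1.0) for r in rates):
        raise ParameterError("mutation rates must lie in [0, 1)")
    if config.genome_length <= 0:
        raise ParameterError("genome length must be positive")
    if not config.strains_per_cluster or any(
        n <= 0 for n in config.strains_per_cluster
    ):
        raise ParameterError("each cluster needs at least one strain")


def _generate_once(
    config: StrainSimConfig, seed: int
) -> tuple[dict[str, str], pd.DataFrame]:
    rng = np.random.default_rng(seed)
    ancestral = _random_genome(config.genome_length, rng)
    seqs: dict[str, str] = {}
    rows = []
    strain_no = 0
    for c, n_strains in enumerate(config.strains_per_cluster, start=1):
        cluster_ancestor, _ = _mutate(
            ancestral,
            config.between_sub_rate,
            config.between_indel_rate,
            config.indel_length_p,
            config.cluster_segment_events,
            config.cluster_segment_events,
            config.segment_length_range,
            rng,
        )
        for _s in range(n_strains):
            strain_no += 1
            sid = f"S{strain_no:02d}"
            seq, stats = _mutate(
                cluster_ancestor,
                config.within_sub_rate,
                config.within_indel_rate,
                config.indel_length_p,
                config.strain_segment_events,
                config.strain_segment_events,
                config.segment_length_range,
                rng,
            )
            seqs[sid] = seq
            rows.append(
                {
                    "strain_id": sid,
                    "cluster_id": f"T{c}",
                    "length": len(seq),
                    **stats,
                }
            )
    return seqs, pd.DataFrame(rows)


def _check_similarity(
    seqs: dict[str, str], manifest: pd.DataFrame, config: StrainSimConfig
) -> tuple[bool, float, float]:
    kmers = {
        sid: extract_canonical_kmers([(sid, seq)], config.k, genome_id=sid)
        for sid, seq in seqs.items()
    }
    cluster_of = dict(zip(manifest.strain_id, manifest.cluster_id))
    ids = list(seqs)
    min_within, max_between = 1.0, 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            jac = jaccard(kmers[ids[i]], kmers[ids[j]])
            if cluster_of[ids[i]] == cluster_of[ids[j]]:
                min_within = min(min_within, jac)
            else:
                max_between = max(max_between, jac)
    ok = min_within >= config.target_within and max_between < config.target_between
    return ok, min_within, max_between


def generate_strain_set(config: StrainSimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Strain sequences plus a truth manifest; deterministic per seed.

    The realized k-mer Jaccard structure is verified against the configured
    within/between-cluster targets; on a miss the set is regenerated with
    gently nudged rates up to ``max_retries`` times before erroring out.
    """
    _validate_sim_config(config)
    cfg = config
    for attempt in range(config.max_retries + 1):
        seqs, manifest = _generate_once(cfg, config.seed + 7919 * attempt)
        ok, min_within, max_between = _check_similarity(seqs, manifest, config)
        if ok:
            return seqs, manifest
        logger.warning(
            "similarity targets missed (min within %.4f, max between %.4f); "
            "retrying with adjusted rates",
            min_within,
            max_between,
        )
        cfg = replace(
            cfg,
            within_sub_rate=cfg.within_sub_rate
            * (0.7 if min_within < config.target_within else 1.0),
            between_sub_rate=cfg.between_sub_rate
            * (1.3 if max_between >= config.target_between else 1.0),
        )
    raise StrainSiftError(
        "could not reach the configured Jaccard similarity structure; "
        "lower within-cluster or raise between-cluster mutation rates"
    )


def simulate_strain_set(
    config: StrainSimConfig, out_dir: str | Path
) -> tuple[list[Path], Path]:
    """Write one FASTA per strain plus ``manifest.tsv``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, manifest = generate_strain_set(config)
    paths = []
    for sid, seq in seqs.items():
        p = out_dir / f"{sid}.fasta"
        write_fasta(p, [(sid, seq)])
        paths.append(p)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return paths, manifest_path


def generate_read_pairs(
    genome: str, config: ReadSimConfig
) -> list[tuple[str, str]] | list[str]:
    """In-memory read simulation from one genome.

    Paired mode returns (R1, R2) tuples in FR orientation; fragment lengths
    are normal(mean, sd) truncated to [read length, genome length].
    """
    if config.depth <= 0:
        raise ParameterError("depth must be positive")
    L = len(genome)
    rl = config.read_length
    if L <= config.fragment_mean:
        raise ParameterError("genome must be longer than the mean fragment")
    rng = np.random.default_rng(config.seed)
    n_pairs = max(1, round(config.depth * L / ((2 if config.paired else 1) * rl)))
    frags = rng.normal(config.fragment_mean, config.fragment_sd, size=4 * n_pairs)
    frags = frags[(frags >= rl) & (frags <= L)].astype(int)
    while frags.size < n_pairs:
        extra = rng.normal(config.fragment_mean, config.fragment_sd, size=n_pairs)
        frags = np.concatenate([frags, extra[(extra >= rl) & (extra <= L)].astype(int)])
    frags = frags[:n_pairs]
    starts = (rng.random(n_pairs) * (L - frags + 1)).astype(int)

    def with_errors(seq: str) -> str:
        if config.error_rate <= 0:
            return seq
        arr = np.array(list(seq))
        hit = rng.random(arr.size) < config.error_rate
        if hit.any():
            idx = np.nonzero(hit)[0]
            for p in idx:
                choices = [b for b in "ACGT" if b != arr[p]]
                arr[p] = choices[rng.integers(0, 3)]
        return "".join(arr)

    if config.paired:
        out_pairs: list[tuple[str, str]] = []
        for s, f in zip(starts, frags):
            frag = genome[s : s + f]
            out_pairs.append((with_errors(frag[:rl]), with_errors(revcomp(frag[-rl:]))))
        return out_pairs
    out_single: list[str] = []
    for s, f in zip(starts, frags):
        frag = genome[s : s + f]
        out_single.append(with_errors(frag[:rl]))
    return out_single


def simulate_reads(
    fasta_or_seq: str | Path,
    config: ReadSimConfig,
    out_prefix: str | Path,
    *,
    read_id_prefix: str = "read",
) -> list[Path]:
    """Simulate reads from a genome FASTA (or raw sequence) to FASTQ files."""
    looks_like_path = isinstance(fasta_or_seq, Path)
    if not looks_like_path and isinstance(fasta_or_seq, str) and len(fasta_or_seq) < 4096:
        try:
            looks_like_path = Path(fasta_or_seq).exists()
        except OSError:
            looks_like_path = False
    if looks_like_path:
        from .io import read_fasta

        genome = "".join(seq for _id, seq in read_fasta(fasta_or_seq))
    else:
        genome = str(fasta_or_seq)
    reads = generate_read_pairs(genome, config)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if config.paired:
        p1 = out_prefix.with_name(out_prefix.name + "_1.fastq")
        p2 = out_prefix.with_name(out_prefix.name + "_2.fastq")
        write_fastq(p1, ((f"{read_id_prefix}{i}/1", r1) for i, (r1, _r2) in enumerate(reads)))
        write_fastq(p2, ((f"{read_id_prefix}{i}/2", r2) for i, (_r1, r2) in enumerate(reads)))
        return [p1, p2]
    p = out_prefix.with_name(out_prefix.name + ".fastq")
    write_fastq(p, ((f"{read_id_prefix}{i}", r) for i, r in enumerate(reads)))
    return [p]


def simulate_mixture(
    genomes: dict[str, str],
    depths: dict[str, float],
    config: ReadSimConfig,
) -> tuple[list[str], dict[str, float]]:
    """Shuffled pooled reads from several strains plus the truth profile.

    Truth relative abundance of strain i is depth_i·length_i normalized over
    the mixture (sequence mass, matching what the reads contain).  Returns
    flat read sequences (pairs interleaved) and the truth profile.
    """
    if set(genomes) != set(depths):
        raise InputError("depth profile does not match the strain set")
    if any(d <= 0 for d in depths.values()):
        raise ParameterError("all depths must be positive")
    rng = np.random.default_rng(config.seed)
    reads: list[str] = []
    mass: dict[str, float] = {}
    for sid in sorted(genomes):
        sub = replace(
            config, depth=depths[sid], seed=int(rng.integers(0, 2**31 - 1))
        )
        r = generate_read_pairs(genomes[sid], sub)
        if config.paired:
            for r1, r2 in r:  # type: ignore[misc]
                reads.extend((r1, r2))
        else:
            reads.extend(r)  # type: ignore[arg-type]
        mass[sid] = depths[sid] * len(genomes[sid])
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    total = sum(mass.values())
    return reads, {sid: m / total for sid, m in mass.items()}
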