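"""Gzip-transparent FASTA/FASTQ reading and writing (Biopython-backed)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError


def open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All (id, sequence) records of a FASTA file."""
    with open_text(path) as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file, reporting the failing record."""
    with open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        i = 0
        while True:
            try:
                title_seq_qual = next(it, None)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed FASTQ at record {i}: {exc}") from exc
            if title_seq_qual is None:
                return
            yield title_seq_qual[1]
            i += 1


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open_text(path, "wt") as out:
        for rec_id, seq in records:
            out.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) reads with a constant maximum-quality string."""
    with open_text(path, "wt") as out:
        for rec_id, seq in reads:
            out.write(f"@{rec_id}\n{seq}\n+\n{'I' * len(seq)}\n")
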