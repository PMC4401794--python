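"""Sequence I/O helpers: FASTA/FASTQ reading and writing, gz-transparent.

Thin wrappers around :mod:`Bio.SeqIO` that keep the rest of the package
working on plain ``(name, sequence)`` pairs and on :class:`RawRead`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class RawRead:
    """A single raw sequencing read (quality optional, never used)."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")


def revcomp(seq: str) -> str:
    """Reverse complement; U is treated as T, N stays N."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path) -> dict[str, str]:
    """Load a FASTA/FASTQ file into an ordered {name: sequence} dict."""
    fmt = _sniff_format(path)
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            out[rec.id] = str(rec.seq).upper().replace("U", "T")
    return out


def read_raw(path: str | Path) -> Iterator[RawRead]:
    """Stream raw reads from FASTA or FASTQ (gz-transparent)."""
    fmt = _sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                scores = rec.letter_annotations.get("phred_quality")
                if scores is not None:
                    qual = "".join(chr(q + 33) for q in scores)
            yield RawRead(rec.id, str(rec.seq).upper(), qual)


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(path: str | Path, reads: Iterable[RawRead]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")
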