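"""Raw-read cleaning: adapter trimming, length filter, junk filter, collapse.

Pipeline order is fixed (adapter -> length -> junk -> collapse) so every
raw read is assigned exactly one fate and the accounting report sums back
to the raw total, for both totals and unique sequence counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .seqio import VALID_BASES, RawRead

MIN_TAG_LEN = 18
MAX_TAG_LEN = 26

#: junk rules in evaluation order: (label, kind, parameter)
#: run rules flag maximal homopolymer runs; repeat rules flag consecutive
#: tandem copies of one non-homopolymeric k-mer unit.
JUNK_RULES: tuple[tuple[str, str, int, int], ...] = (
    (">=2N", "ncount", 0, 2),
    (">=7A", "run", ord("A"), 7),
    (">=8C", "run", ord("C"), 8),
    (">=6G", "run", ord("G"), 6),
    (">=7T", "run", ord("T"), 7),
    (">=10 Dimer", "repeat", 2, 10),
    (">=6 Trimer", "repeat", 3, 6),
    (">=5 Tetramer", "repeat", 4, 5),
)


@dataclass(frozen=True)
class UniqueTag:
    """A distinct clean sequence with its per-library read count."""

    sequence: str
    count: int


@dataclass
class CleaningReport:
    """Per-fate read accounting (totals and unique-sequence counts)."""

    raw_total: int = 0
    raw_unique: int = 0
    adapter_length_total: int = 0
    adapter_length_unique: int = 0
    junk_total: int = 0
    junk_unique: int = 0
    clean_total: int = 0
    clean_unique: int = 0
    junk_reasons: Counter = field(default_factory=Counter)

    def percentage(self, part: int) -> float:
        """Percentage of raw reads, rounded to 2 decimals."""
        return clean_percentage(part, self.raw_total)

    def to_rows(self) -> list[dict]:
        rows = [
            ("Raw reads", self.raw_total, self.raw_unique),
            ("3'ADT&length", self.adapter_length_total, self.adapter_length_unique),
            ("Junk reads", self.junk_total, self.junk_unique),
            ("Clean reads", self.clean_total, self.clean_unique),
        ]
        return [
            {
                "item": item,
                "total": total,
                "total_pct": self.percentage(total),
                "unique": uniq,
            }
            for item, total, uniq in rows
        ]


def clean_percentage(part: int, whole: int) -> float:
    """100 * part / whole rounded to 2 decimals (report convention)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, 2)


def trim_adapter(read: RawRead | str, adapter: str, min_overlap: int = 8) -> str | None:
    """Return the insert preceding the leftmost 3' adapter match, or None.

    The adapter may run off the end of the read, so any prefix of the
    adapter of length >= ``min_overlap`` counts as a match; shorter
    terminal prefixes do not. ``None`` means "3' adapter not found" and
    the read is discarded.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require 1 <= min_overlap <= len(adapter)")
    seq = read.sequence if isinstance(read, RawRead) else read
    probe = adapter[:min_overlap]
    pos = seq.find(probe)
    while pos != -1:
        tail = seq[pos:]
        if adapter.startswith(tail) or tail.startswith(adapter):
            return seq[:pos]
        pos = seq.find(probe, pos + 1)
    return None


def length_pass(sequence: str) -> bool:
    """True iff 18 <= length <= 26."""
    return MIN_TAG_LEN <= len(sequence) <= MAX_TAG_LEN


def _max_run(seq: str, base: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == base else 0
        best = max(best, cur)
    return best


def _max_tandem_copies(seq: str, unit_len: int) -> int:
    """Longest run of consecutive tandem copies of any non-homopolymer unit."""
    n = len(seq)
    best = 0
    for start in range(n - unit_len + 1):
        unit = seq[start : start + unit_len]
        if len(set(unit)) == 1:  # homopolymer units governed by run rules
            continue
        copies = 1
        pos = start + unit_len
        while seq[pos : pos + unit_len] == unit:
            copies += 1
            pos += unit_len
        best = max(best, copies)
    return best


def junk_reason(sequence: str) -> str | None:
    """First violated junk rule label, or None when the sequence is clean.

    Rules, in order: total N count >= 2; homopolymer runs >=7A, >=8C,
    >=6G, >=7T; tandem repeats of a 2-mer unit >=10 copies, a 3-mer
    unit >=6 copies, or a 4-mer unit >=5 copies.
    """
    if set(sequence) - VALID_BASES:
        bad = sorted(set(sequence) - VALID_BASES)
        raise ValueError(f"invalid characters in sequence: {bad}")
    for label, kind, param, threshold in JUNK_RULES:
        if kind == "ncount":
            if sequence.count("N") >= threshold:
                return label
        elif kind == "run":
            if _max_run(sequence, chr(param)) >= threshold:
                return label
        else:
            if _max_tandem_copies(sequence, param) >= threshold:
                return label
    return None


def clean_library(
    reads: Iterable[RawRead],
    adapter: str,
    min_overlap: int = 8,
) -> tuple[list[UniqueTag], CleaningReport]:
    """Adapter-trim, length-filter, junk-filter and collapse a read stream.

    Returns unique clean tags sorted by (-count, sequence) and the
    accounting report. Raises on an empty stream.
    """
    report = CleaningReport()
    raw_seqs: set[str] = set()
    removed_al: set[str] = set()
    removed_junk: set[str] = set()
    counts: Counter[str] = Counter()

    for read in reads:
        report.raw_total += 1
        raw_seqs.add(read.sequence)
        insert = trim_adapter(read, adapter, min_overlap)
        if insert is None or not length_pass(insert):
            report.adapter_length_total += 1
            removed_al.add(read.sequence)
            continue
        reason = junk_reason(insert)
        if reason is not None:
            report.junk_total += 1
            report.junk_reasons[reason] += 1
            removed_junk.add(read.sequence)
            continue
        report.clean_total += 1
        counts[insert] += 1

    if report.raw_total == 0:
        raise ValueError("empty read stream")

    report.raw_unique = len(raw_seqs)
    report.adapter_length_unique = len(removed_al)
    report.junk_unique = len(removed_junk)
    report.clean_unique = len(counts)
    tags = [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return tags, report


def write_tags_fasta(path, tags: list[UniqueTag]) -> None:
    """Collapsed-tag FASTA with ``>tag{i}_x{count}`` headers."""
    from .seqio import write_fasta

    write_fasta(path, ((f"tag{i}_x{t.count}", t.sequence) for i, t in enumerate(tags, 1)))


def write_report_tsv(path, report: CleaningReport) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["item", "total", "total_pct", "unique"], delimiter="\t"
        )
        writer.writeheader()
        for row in report.to_rows():
            writer.writerow(row)
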