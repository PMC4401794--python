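"""Contaminant annotation: assign clean tags to reference categories.

Tags are short (18-26 nt), so matching is an ungapped full-tag substring
scan with at most one substitution, on both strands — no aligner index
needed at this scale. Categories are made disjoint by a configurable
priority order; each tag gets exactly one fate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .read_cleaning import UniqueTag
from .seqio import revcomp

DEFAULT_PRIORITY = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "other_ncRNA",
    "mRNA",
    "repeats",
)


@dataclass(frozen=True)
class ReferenceHit:
    ref_id: str
    position: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class CategoryAssignment:
    sequence: str
    category: str  # a reference category or "retained"
    ref_id: str | None = None


def _best_substring_hit(query: str, ref: str, max_mismatch: int) -> tuple[int, int] | None:
    """Best (mismatches, position) for an ungapped end-to-end placement."""
    qlen = len(query)
    best: tuple[int, int] | None = None
    for pos in range(len(ref) - qlen + 1):
        mism = 0
        window = ref[pos : pos + qlen]
        for a, b in zip(query, window):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            if best is None or mism < best[0]:
                best = (mism, pos)
                if mism == 0:
                    return best
    return best


def match_reference(
    tag: str, refset: Mapping[str, str], max_mismatch: int = 1
) -> ReferenceHit | None:
    """Best end-to-end ungapped hit of the tag in a reference set.

    Both strands are searched; ties resolved by fewest mismatches, then
    lexicographically smallest reference id, then '+' strand.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if not refset:
        raise ValueError("empty reference set")
    best: ReferenceHit | None = None
    rc = revcomp(tag)
    for ref_id in sorted(refset):
        ref = refset[ref_id]
        for strand, query in (("+", tag), ("-", rc)):
            hit = _best_substring_hit(query, ref, max_mismatch)
            if hit is None:
                continue
            mism, pos = hit
            if best is None or (mism, ref_id, strand) < (
                best.mismatches,
                best.ref_id,
                best.strand,
            ):
                best = ReferenceHit(ref_id, pos, strand, mism)
    return best


@dataclass
class AnnotationReport:
    """Per-category totals/uniques with percentages of the raw total."""

    rows: list[dict]

    def category_total(self, category: str) -> int:
        for row in self.rows:
            if row["category"] == category:
                return row["total"]
        raise KeyError(category)


def classify_tags(
    tags: Sequence[UniqueTag],
    references: Mapping[str, Mapping[str, str]],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    max_mismatch: int = 0,
    raw_total: int | None = None,
) -> tuple[list[UniqueTag], AnnotationReport, list[CategoryAssignment]]:
    """Partition tags into contaminant categories plus a retained set.

    Each tag is assigned to the first category in ``priority`` whose
    reference set it hits; unhit tags are retained for miRNA analysis.
    ``raw_total`` (when given) is the denominator for report percentages,
    mirroring a raw-read accounting table; otherwise the tag total is used.
    """
    if sorted(set(priority)) != sorted(priority):
        raise ValueError("priority must list each category once")
    missing = [c for c in priority if c not in references]
    if missing:
        raise ValueError(f"missing reference sets for categories: {missing}")

    retained: list[UniqueTag] = []
    assignments: list[CategoryAssignment] = []
    totals = {c: 0 for c in priority}
    uniques = {c: 0 for c in priority}
    for tag in tags:
        assigned = None
        for category in priority:
            refset = references[category]
            if not refset:
                continue
            hit = match_reference(tag.sequence, refset, max_mismatch)
            if hit is not None:
                assigned = CategoryAssignment(tag.sequence, category, hit.ref_id)
                totals[category] += tag.count
                uniques[category] += 1
                break
        if assigned is None:
            assigned = CategoryAssignment(tag.sequence, "retained")
            retained.append(tag)
        assignments.append(assigned)

    denom = raw_total if raw_total is not None else sum(t.count for t in tags)
    rows = []
    for category in priority:
        rows.append(
            {
                "category": category,
                "total": totals[category],
                "total_pct": round(100.0 * totals[category] / denom, 2) if denom else 0.0,
                "unique": uniques[category],
                "unique_pct": 0.0,
            }
        )
    kept_total = sum(t.count for t in retained)
    rows.append(
        {
            "category": "retained",
            "total": kept_total,
            "total_pct": round(100.0 * kept_total / denom, 2) if denom else 0.0,
            "unique": len(retained),
            "unique_pct": 0.0,
        }
    )
    if denom:
        n_unique = len(tags)
        for row in rows:
            row["unique_pct"] = round(100.0 * row["unique"] / n_unique, 2) if n_unique else 0.0
    return retained, AnnotationReport(rows), assignments


def write_annotation_tsv(path, report: AnnotationReport) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["category", "total", "total_pct", "unique", "unique_pct"],
            delimiter="\t",
        )
        writer.writeheader()
        for row in report.rows:
            writer.writerow(row)
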