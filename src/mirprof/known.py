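"""Known-miRNA identification: <=1-mismatch matching and variant naming.

A tag is matched against each mature reference in the context of its
precursor, allowing the tag's ends to be shifted by up to ``max_offset``
bases into the precursor (isomiR ends) and at most one substitution.
Variant names encode the end offsets and the substitution, e.g.
``base_L+1R-1`` or ``base_R+1_1ss12TA`` (position 12, ref T observed A).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation import match_reference
from .read_cleaning import UniqueTag

GROUP_LABELS = ("gp1b", "gp2a", "gp3a", "gp4a")


@dataclass(frozen=True)
class Substitution:
    position: int  # 1-based on the tag
    ref_base: str
    obs_base: str


@dataclass(frozen=True)
class MirnaMatch:
    tag: str
    mature_id: str
    precursor_id: str
    offset5: int  # L offset: +n = tag starts n nt upstream of the mature 5' end
    offset3: int  # R offset: +n = tag ends n nt downstream of the mature 3' end
    substitutions: tuple[Substitution, ...] = ()

    @property
    def name(self) -> str:
        return variant_name(self.mature_id, self.offset5, self.offset3, self.substitutions)


def variant_name(
    base_id: str,
    offset5: int,
    offset3: int,
    substitutions: Sequence[Substitution] = (),
) -> str:
    """Canonical isomiR name: base, then _L±n / R±n, then _1ss{pos}{ref}{obs}."""
    name = base_id
    if offset5 or offset3:
        part = "_"
        if offset5:
            part += f"L{offset5:+d}"
        if offset3:
            part += f"R{offset3:+d}"
        name += part
    for sub in substitutions:
        name += f"_1ss{sub.position}{sub.ref_base}{sub.obs_base}"
    return name


_NAME_RE = re.compile(
    r"^(?P<base>.*?)"
    r"(?:_(?=[LR])(?:L(?P<l>[+-]\d+))?(?:R(?P<r>[+-]\d+))?)?"
    r"(?P<subs>(?:_1ss\d+[ACGTN][ACGTN])*)$"
)


def parse_variant_name(name: str) -> tuple[str, int, int, tuple[Substitution, ...]]:
    """Inverse of :func:`variant_name` (used for round-trip checks)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable variant name: {name!r}")
    subs = tuple(
        Substitution(int(pos), ref, obs)
        for pos, ref, obs in re.findall(r"_1ss(\d+)([ACGTN])([ACGTN])", m.group("subs"))
    )
    return (
        m.group("base"),
        int(m.group("l") or 0),
        int(m.group("r") or 0),
        subs,
    )


def _locate_mature(mature: str, precursors: Mapping[str, str]) -> tuple[str, int] | None:
    for pid in sorted(precursors):
        pos = precursors[pid].find(mature)
        if pos != -1:
            return pid, pos
    return None


def match_known(
    tag: str,
    matures: Mapping[str, str],
    precursors: Mapping[str, str],
    max_mismatch: int = 1,
    max_offset: int = 3,
) -> MirnaMatch | None:
    """Best known-miRNA assignment for a tag, or None.

    For every mature located on a precursor, the tag is compared with the
    precursor window obtained by shifting the mature's ends by (dL, dR)
    with |dL|,|dR| <= max_offset; a candidate needs <= ``max_mismatch``
    substitutions. Ties are broken by (mismatches, |dL|+|dR|, mature id).
    """
    best: tuple[tuple[int, int, str], MirnaMatch] | None = None
    for mid in sorted(matures):
        mature = matures[mid]
        located = _locate_mature(mature, precursors)
        if located is None:
            continue
        pid, mstart = located
        precursor = precursors[pid]
        mend = mstart + len(mature)
        for d5 in range(-max_offset, max_offset + 1):
            for d3 in range(-max_offset, max_offset + 1):
                start = mstart - d5
                end = mend + d3
                if end - start != len(tag):
                    continue
                if start < 0 or end > len(precursor):
                    continue
                window = precursor[start:end]
                subs = [
                    Substitution(i + 1, rb, tb)
                    for i, (rb, tb) in enumerate(zip(window, tag))
                    if rb != tb
                ]
                if len(subs) > max_mismatch:
                    continue
                key = (len(subs), abs(d5) + abs(d3), mid)
                if best is None or key < best[0]:
                    best = (key, MirnaMatch(tag, mid, pid, d5, d3, tuple(subs)))
    return best[1] if best else None


@dataclass
class GroupContext:
    """Everything :func:`assign_group` needs beyond the match itself."""

    genome: Mapping[str, str]
    precursors: Mapping[str, str]
    hairpin_check: "callable"  # (tag sequence) -> bool: locus extension folds into a hairpin
    _cache: dict = field(default_factory=dict)

    def maps_to_genome(self, seq: str) -> bool:
        hit = self._cache.get(seq)
        if hit is None:
            hit = match_reference(seq, self.genome, max_mismatch=0) is not None
            self._cache[seq] = hit
        return hit


def assign_group(tag: str, match: MirnaMatch | None, ctx: GroupContext) -> str | None:
    """Evidence group for a (possibly matched) tag; None = not reportable.

    gp1b: matched and the precursor maps to the genome.
    gp2a: matched, precursor unmapped, tag maps and its extension folds.
    gp3a: matched, neither precursor nor tag maps (fallback for matched
          tags whose genomic extension does not fold).
    gp4a: unmatched, tag maps and its extension folds.
    """
    if match is not None:
        precursor = ctx.precursors[match.precursor_id]
        if ctx.maps_to_genome(precursor):
            return "gp1b"
        if ctx.maps_to_genome(tag) and ctx.hairpin_check(tag):
            return "gp2a"
        return "gp3a"
    if ctx.maps_to_genome(tag) and ctx.hairpin_check(tag):
        return "gp4a"
    return None


@dataclass(frozen=True)
class KnownMirnaRecord:
    name: str
    group: str
    counts: tuple[int, ...]  # one entry per library


def identify_known(
    tag_sets: Sequence[Sequence[UniqueTag]],
    matures: Mapping[str, str],
    precursors: Mapping[str, str],
    ctx: GroupContext | None = None,
    max_mismatch: int = 1,
    max_offset: int = 3,
) -> tuple[list[KnownMirnaRecord], list[set[str]], dict[str, list[UniqueTag]]]:
    """Match every tag in every library; aggregate counts per variant name.

    Returns (records sorted by name, per-library detected-name sets,
    unmatched tags per library keyed by library index as str).
    """
    n_libs = len(tag_sets)
    counts: dict[str, list[int]] = {}
    groups: dict[str, str] = {}
    detected: list[set[str]] = [set() for _ in range(n_libs)]
    unmatched: dict[str, list[UniqueTag]] = {str(i): [] for i in range(n_libs)}
    match_cache: dict[str, MirnaMatch | None] = {}
    group_cache: dict[str, str | None] = {}

    for lib, tags in enumerate(tag_sets):
        for tag in tags:
            if tag.sequence not in match_cache:
                match_cache[tag.sequence] = match_known(
                    tag.sequence, matures, precursors, max_mismatch, max_offset
                )
            match = match_cache[tag.sequence]
            if match is None:
                unmatched[str(lib)].append(tag)
                continue
            name = match.name
            if name not in counts:
                counts[name] = [0] * n_libs
                if ctx is not None:
                    if tag.sequence not in group_cache:
                        group_cache[tag.sequence] = assign_group(tag.sequence, match, ctx)
                    groups[name] = group_cache[tag.sequence] or "gp3a"
                else:
                    groups[name] = "gp3a"
            counts[name][lib] += tag.count
            detected[lib].add(name)

    records = [
        KnownMirnaRecord(name, groups[name], tuple(counts[name]))
        for name in sorted(counts)
    ]
    return records, detected, unmatched
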