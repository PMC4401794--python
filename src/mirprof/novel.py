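"""Novel-miRNA candidate evaluation: flank extraction, folding, filters.

The built-in folder is a Nussinov-style dynamic program maximizing a
weighted base-pair count (GC=3, AU=2, GU=1, minimum loop 3); free energy
is reported as ``-CALIBRATION * score`` kcal/mol. Any callable with the
same ``seq -> (dot_bracket, dG)`` contract can be substituted (e.g. a
thermodynamic folder); results are deterministic per backend.

Candidate precursors are the hairpin-spanning subwindow of a folded
search window (the 80-nt flanks are a search window, not the precursor).
Filters: precursor length 50-123 nt, GC fraction 0.23-0.77, free energy
-80.5..-17.7 kcal/mol, a single terminal loop, and the mature entirely
on one arm with a bounded number of unpaired mature bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .seqio import revcomp

#: kcal/mol subtracted per unit of pair weight by the built-in folder;
#: chosen so well-formed 50-123 nt hairpins land inside the dG filter.
CALIBRATION = 0.5

MIN_PRECURSOR = 50
MAX_PRECURSOR = 123
GC_MIN, GC_MAX = 0.23, 0.77
DG_MIN, DG_MAX = -80.5, -17.7
DEFAULT_MAX_UNPAIRED_MATURE = 4
MIN_LOOP = 3

_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}

FoldBackend = Callable[[str], tuple[str, float]]


@dataclass(frozen=True)
class HairpinCandidate:
    contig: str
    start: int  # 0-based half-open locus of the precursor
    end: int
    strand: str
    sequence: str
    structure: str
    dg: float
    gc_fraction: float
    arm: str  # '5p' or '3p'
    mature_start: int  # within the precursor
    mature: str

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure length != sequence length")


def _normalize(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGTN"):
        raise ValueError("invalid characters for folding")
    return seq


def fold(sequence: str) -> tuple[str, float]:
    """Maximum-weight nested pairing of a sequence (built-in backend).

    Returns (dot-bracket structure, dG in kcal/mol). dG is 0 when no
    pairs form. T and U are equivalent; N never pairs.
    """
    seq = _normalize(sequence)
    n = len(seq)
    if n == 0:
        return "", 0.0
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.intp)
    for idx, base in enumerate("ACGT"):
        lut[ord(base)] = idx + 1  # 0 = N (never pairs)
    enc = lut[codes]
    wtab = np.zeros((5, 5), dtype=np.int64)
    for (a, b), weight in _PAIR_WEIGHT.items():
        wtab["_ACGT".index(a), "_ACGT".index(b)] = weight

    # DP on diagonals (contiguous views) for speed; diag[d][i] = m[i, i+d]
    diag: list[np.ndarray] = [np.zeros(n - d, dtype=np.int64) for d in range(n)]
    for d in range(MIN_LOOP + 1, n):
        length = n - d
        wd = wtab[enc[:length], enc[d:]]
        best = np.maximum(diag[d - 1][1:], diag[d - 1][:length])
        paired = diag[d - 2][1 : length + 1] + wd
        best = np.maximum(best, np.where(wd > 0, paired, -1))
        for s in range(MIN_LOOP + 1, d - MIN_LOOP - 1):
            np.maximum(best, diag[s][:length] + diag[d - s - 1][s + 1 : s + 1 + length], out=best)
        diag[d] = best

    m = np.zeros((n, n), dtype=np.int64)
    w = np.zeros((n, n), dtype=np.int64)
    for d in range(1, n):
        idx = np.arange(n - d)
        m[idx, idx + d] = diag[d]
        if d > MIN_LOOP:
            w[idx, idx + d] = wtab[enc[: n - d], enc[d:]]

    structure = ["."] * n
    score = 0
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or m[i, j] == 0:
            continue
        if m[i, j] == m[i + 1, j]:
            stack.append((i + 1, j))
        elif m[i, j] == m[i, j - 1]:
            stack.append((i, j - 1))
        elif w[i, j] > 0 and m[i, j] == m[i + 1, j - 1] + w[i, j]:
            structure[i] = "("
            structure[j] = ")"
            score += int(w[i, j])
            stack.append((i + 1, j - 1))
        else:
            for k in range(i, j):
                if m[i, j] == m[i, k] + m[k + 1, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return "".join(structure), -CALIBRATION * score if score else 0.0


def extract_flanks(
    genome: Mapping[str, str],
    contig: str,
    start: int,
    end: int,
    strand: str = "+",
    flank: int = 80,
) -> list[tuple[int, int, str]]:
    """Candidate windows around a tag locus: left-, right-, both-extended.

    Returns (window_start, window_end, window_sequence) triples in plus-
    strand coordinates, clipped at contig ends; the sequence is reverse
    complemented for minus-strand loci. Duplicate windows (after
    clipping) are dropped.
    """
    if contig not in genome:
        raise KeyError(f"contig {contig!r} not in genome")
    seq = genome[contig]
    if not (0 <= start < end <= len(seq)):
        raise ValueError("locus outside contig")
    lo = max(0, start - flank)
    hi = min(len(seq), end + flank)
    spans = [(lo, end), (start, hi), (lo, hi)]
    out: list[tuple[int, int, str]] = []
    seen = set()
    for a, b in spans:
        if (a, b) in seen:
            continue
        seen.add((a, b))
        window = seq[a:b]
        if strand == "-":
            window = revcomp(window)
        out.append((a, b, window))
    return out


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 = unpaired); checks balance."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            table[i], table[j] = j, i
    if stack:
        raise ValueError("unbalanced structure")
    return table


def terminal_loops(structure: str) -> list[tuple[int, int]]:
    """(lo, hi) spans of maximal unpaired runs flanked by '(' and ')'."""
    return [
        (m.start() + 1, m.end() - 1)
        for m in re.finditer(r"\((\.+)\)", structure)
    ]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def trim_to_hairpin(sequence: str, structure: str) -> tuple[int, int]:
    """Span (start, end) of the outermost paired bases, half-open."""
    first = structure.find("(")
    last = structure.rfind(")")
    if first == -1 or last == -1:
        return 0, 0
    return first, last + 1


def evaluate_candidate(
    window: str,
    structure: str,
    dg: float,
    mature: str,
    max_unpaired_mature: int = DEFAULT_MAX_UNPAIRED_MATURE,
) -> tuple[bool, list[str], dict | None]:
    """Apply the precursor filters to a folded window.

    Returns (pass, reasons, details). ``details`` (on pass) carries the
    trimmed precursor span/sequence/structure, arm, and mature placement.
    The reasons list names every violated rule and is empty iff pass.
    """
    window = _normalize(window)
    mature = _normalize(mature)
    mpos = window.find(mature)
    if mpos == -1:
        raise ValueError("mature sequence not found in window")

    reasons: list[str] = []
    lo, hi = trim_to_hairpin(window, structure)
    precursor = window[lo:hi]
    pstruct = structure[lo:hi]
    plen = hi - lo

    if plen < MIN_PRECURSOR:
        reasons.append(f"length<{MIN_PRECURSOR}")
    if plen > MAX_PRECURSOR:
        reasons.append(f"length>{MAX_PRECURSOR}")
    gc = gc_fraction(precursor)
    if gc < GC_MIN:
        reasons.append(f"GC<{GC_MIN}")
    if gc > GC_MAX:
        reasons.append(f"GC>{GC_MAX}")
    if dg < DG_MIN:
        reasons.append(f"dG<{DG_MIN}")
    if dg > DG_MAX:
        reasons.append(f"dG>{DG_MAX}")

    loops = terminal_loops(pstruct)
    arm = None
    m_lo, m_hi = mpos - lo, mpos - lo + len(mature)
    if len(loops) != 1:
        reasons.append("not a single terminal loop")
    else:
        loop_lo, loop_hi = loops[0]
        if m_lo < 0 or m_hi > plen:
            reasons.append("mature outside precursor")
        elif m_hi <= loop_lo:
            arm = "5p"
        elif m_lo >= loop_hi:
            arm = "3p"
        else:
            reasons.append("mature spans the terminal loop")
    if arm is not None:
        unpaired = pstruct[m_lo:m_hi].count(".")
        if unpaired > max_unpaired_mature:
            reasons.append(f"unpaired mature bases>{max_unpaired_mature}")

    ok = not reasons
    details = None
    if ok:
        details = {
            "span": (lo, hi),
            "precursor": precursor,
            "structure": pstruct,
            "dg": dg,
            "gc": gc,
            "arm": arm,
            "mature_start": m_lo,
        }
    return ok, reasons, details


def _stem_span(structure: str, loop: tuple[int, int]) -> tuple[int, int]:
    """Walk the enclosing helix of one terminal loop outward through bulges."""
    table = pair_table(structure)
    i, j = loop[0] - 1, loop[1]
    while True:
        i2, j2 = i - 1, j + 1
        while i2 >= 0 and table[i2] == -1:
            i2 -= 1
        while j2 < len(structure) and table[j2] == -1:
            j2 += 1
        if i2 >= 0 and j2 < len(structure) and table[i2] == j2:
            i, j = i2, j2
        else:
            return i, j + 1


def scan_hairpin(
    genome: Mapping[str, str],
    contig: str,
    start: int,
    end: int,
    strand: str = "+",
    flank: int = 80,
    backend: FoldBackend = fold,
    max_unpaired_mature: int = DEFAULT_MAX_UNPAIRED_MATURE,
) -> HairpinCandidate | None:
    """Search the extended locus of a tag for a passing hairpin precursor.

    Each flank window is folded once; every hairpin element (terminal
    loop plus its enclosing helix) containing or adjacent to the mature
    is refolded in isolation and passed through the filters. The first
    passing candidate (windows in extract_flanks order, loops 5'->3')
    is returned.
    """
    mature = genome[contig][start:end]
    if strand == "-":
        mature = revcomp(mature)
    for wstart, wend, window in extract_flanks(genome, contig, start, end, strand, flank):
        structure, _ = backend(window)
        spans = [trim_to_hairpin(window, structure)]
        for loop in terminal_loops(structure):
            spans.append(_stem_span(structure, loop))
        seen = set()
        for a, b in spans:
            if b - a < MIN_PRECURSOR or (a, b) in seen:
                continue
            seen.add((a, b))
            sub = window[a:b]
            if mature not in sub:
                continue
            sub_struct, sub_dg = backend(sub)
            ok, _, details = evaluate_candidate(
                sub, sub_struct, sub_dg, mature, max_unpaired_mature
            )
            if not ok:
                continue
            lo, hi = details["span"]
            if strand == "+":
                g_start = wstart + a + lo
                g_end = wstart + a + hi
            else:
                g_start = wend - (a + hi)
                g_end = wend - (a + lo)
            return HairpinCandidate(
                contig=contig,
                start=g_start,
                end=g_end,
                strand=strand,
                sequence=details["precursor"],
                structure=details["structure"],
                dg=details["dg"],
                gc_fraction=details["gc"],
                arm=details["arm"],
                mature_start=details["mature_start"],
                mature=mature,
            )
    return None


_PC_NAME_RE = re.compile(r"^PC-(5p|3p)-(\d+)_(\d+)$")


def candidate_name(arm: str, index: int, count: int) -> str:
    """Novel-candidate naming: ``PC-{arm}-{index}_{count}``."""
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    return f"PC-{arm}-{index}_{count}"


def parse_candidate_name(name: str) -> tuple[str, int, int]:
    m = _PC_NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable candidate name: {name!r}")
    return m.group(1), int(m.group(2)), int(m.group(3))
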