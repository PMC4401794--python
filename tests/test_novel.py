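import functools
import random

import pytest

from mirprof import novel
from mirprof.novel import (
    candidate_name,
    evaluate_candidate,
    extract_flanks,
    fold,
    gc_fraction,
    pair_table,
    parse_candidate_name,
    scan_hairpin,
    terminal_loops,
)
from mirprof.seqio import revcomp


def brute_force_best_weight(seq: str) -> int:
    """Independent oracle: exhaustive recursion over all nested pairings."""

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i < novel.MIN_LOOP + 1:
            return 0
        options = [best(i + 1, j)]  # i unpaired
        for k in range(i + novel.MIN_LOOP + 1, j + 1):
            w = novel._PAIR_WEIGHT.get((seq[i], seq[k]), 0)
            if w > 0:
                options.append(w + best(i + 1, k - 1) + best(k + 1, j))
        return max(options)

    return best(0, len(seq) - 1)


def structure_weight(seq: str, structure: str) -> int:
    table = pair_table(structure)
    return sum(
        novel._PAIR_WEIGHT.get((seq[i], seq[j]), 0)
        for i, j in enumerate(table)
        if j > i
    )


class TestFold:
    def test_small_hairpin_against_enumeration(self):
        seq = "GGGGAAAACCCC"
        structure, dg = fold(seq)
        assert structure == "((((....))))"
        assert dg < 0
        assert structure_weight(seq, structure) == brute_force_best_weight(seq) == 12

    def test_no_complementary_bases(self):
        structure, dg = fold("AAAAAAAAAAAA")
        assert structure == "." * 12
        assert dg == 0.0

    def test_t_u_equivalence(self):
        seq = "GGCAUGCAAAAGCAUGCC"
        assert fold(seq) == fold(seq.replace("U", "T"))

    @pytest.mark.parametrize("length", [8, 10, 12, 14])
    def test_random_sequences_match_enumeration(self, length):
        rng = random.Random(length)
        for _ in range(15):
            seq = "".join(rng.choice("ACGT") for _ in range(length))
            structure, dg = fold(seq)
            best = brute_force_best_weight(seq)
            assert structure_weight(seq, structure) == best
            assert dg == pytest.approx(-novel.CALIBRATION * best if best else 0.0)

    def test_invalid_characters(self):
        with pytest.raises(ValueError):
            fold("ACGX")

    def test_structure_balanced(self):
        structure, _ = fold("GCGCGCAAAAGCGCGCTTTTGGGCCC")
        pair_table(structure)  # raises if unbalanced


class TestExtractFlanks:
    def test_both_extended_window(self, bundle):
        contig = sorted(bundle.genome)[0]
        windows = extract_flanks(bundle.genome, contig, 100, 122, "+", flank=80)
        spans = [(a, b) for a, b, _ in windows]
        assert (20, 202) in spans
        assert (20, 122) in spans and (100, 202) in spans

    def test_clipped_at_contig_start(self, bundle):
        contig = sorted(bundle.genome)[0]
        windows = extract_flanks(bundle.genome, contig, 10, 32, "+", flank=80)
        assert min(a for a, _, _ in windows) == 0

    def test_minus_strand_revcomp(self, bundle):
        contig = sorted(bundle.genome)[0]
        plus = extract_flanks(bundle.genome, contig, 100, 122, "+", flank=80)
        minus = extract_flanks(bundle.genome, contig, 100, 122, "-", flank=80)
        for (a1, b1, w1), (a2, b2, w2) in zip(plus, minus):
            assert (a1, b1) == (a2, b2)
            assert w2 == revcomp(w1)

    def test_locus_outside_contig(self, bundle):
        contig = sorted(bundle.genome)[0]
        with pytest.raises(ValueError):
            extract_flanks(bundle.genome, contig, -5, 20)
        with pytest.raises(KeyError):
            extract_flanks(bundle.genome, "nope", 0, 20)


def _perfect_hairpin(rng, arm_len, loop_len=8):
    arm = "".join(rng.choice("ACGT") for _ in range(arm_len))
    loop = "".join(rng.choice("AC") for _ in range(loop_len))
    return arm + loop + revcomp(arm), arm[:22]


class TestEvaluateCandidate:
    def test_planted_precursors_pass(self, bundle):
        for mid, pid in sorted(bundle.mature_to_precursor.items()):
            precursor = bundle.precursors[pid]
            structure, dg = fold(precursor)
            ok, reasons, details = evaluate_candidate(
                precursor, structure, dg, bundle.matures[mid]
            )
            assert ok, (mid, reasons)
            assert reasons == []
            assert details["arm"] in ("5p", "3p")
            assert novel.MIN_PRECURSOR <= len(details["precursor"]) <= novel.MAX_PRECURSOR

    def test_too_short_fails(self):
        rng = random.Random(0)
        precursor, mature = _perfect_hairpin(rng, arm_len=20, loop_len=6)  # 46 nt
        structure, dg = fold(precursor)
        ok, reasons, _ = evaluate_candidate(precursor, structure, dg, mature)
        assert not ok
        assert any(r.startswith("length<") for r in reasons)

    def test_low_gc_fails(self):
        rng = random.Random(1)
        arm = "".join(rng.choice("AT") for _ in range(26))
        precursor = arm + "CACACACC"[:6] + revcomp(arm)
        structure, dg = fold(precursor)
        ok, reasons, _ = evaluate_candidate(precursor, structure, dg, arm[:22])
        assert gc_fraction(precursor) < 0.23
        assert not ok
        assert any(r.startswith("GC<") for r in reasons)

    def test_weak_dg_fails(self):
        rng = random.Random(2)
        precursor, mature = _perfect_hairpin(rng, arm_len=26)
        structure, _ = fold(precursor)
        ok, reasons, _ = evaluate_candidate(precursor, structure, -17.0, mature)
        assert not ok
        assert any(r.startswith("dG>") for r in reasons)

    def test_too_stable_dg_fails(self):
        rng = random.Random(3)
        precursor, mature = _perfect_hairpin(rng, arm_len=26)
        structure, _ = fold(precursor)
        ok, reasons, _ = evaluate_candidate(precursor, structure, -81.0, mature)
        assert not ok and any(r.startswith("dG<") for r in reasons)

    def test_mature_not_in_window_error(self):
        rng = random.Random(4)
        precursor, _ = _perfect_hairpin(rng, arm_len=26)
        structure, dg = fold(precursor)
        with pytest.raises(ValueError):
            evaluate_candidate(precursor, structure, dg, "TTTTAAAACCCCGGGGTTTTAA")

    def test_reasons_empty_iff_pass(self, bundle):
        rng = random.Random(5)
        cases = []
        for pid in sorted(bundle.precursors):
            cases.append((bundle.precursors[pid], bundle.matures[
                next(m for m, p in bundle.mature_to_precursor.items() if p == pid)
            ]))
        precursor, mature = _perfect_hairpin(rng, arm_len=20, loop_len=6)
        cases.append((precursor, mature))
        for seq, mat in cases:
            structure, dg = fold(seq)
            ok, reasons, _ = evaluate_candidate(seq, structure, dg, mat)
            assert ok == (reasons == [])

    def test_shuffled_negative_controls(self, bundle):
        pid = sorted(bundle.precursors)[0]
        mid = next(m for m, p in bundle.mature_to_precursor.items() if p == pid)
        mature = bundle.matures[mid]
        precursor = bundle.precursors[pid]
        rng = random.Random(42)
        passes = 0
        for _ in range(100):
            flank = list(precursor.replace(mature, ""))
            rng.shuffle(flank)
            shuffled = mature + "".join(flank)  # keep the mature intact
            structure, dg = fold(shuffled)
            ok, _, _ = evaluate_candidate(shuffled, structure, dg, mature)
            passes += ok
        assert passes < 25


class TestScanHairpin:
    def test_finds_planted_novel_loci(self, bundle):
        novel_loci = [loc for loc in bundle.loci if loc.kind == "novel"]
        assert novel_loci
        for loc in novel_loci:
            mature = bundle.novel_matures[loc.element.replace("-pre", "")]
            start = bundle.genome[loc.contig].find(mature, loc.start)
            cand = scan_hairpin(
                bundle.genome, loc.contig, start, start + len(mature), "+"
            )
            assert cand is not None, loc.element
            assert cand.mature == mature
            assert cand.contig == loc.contig
            # reported locus slices back to the reported precursor
            assert (
                bundle.genome[cand.contig][cand.start : cand.end] == cand.sequence
            )

    def test_random_locus_usually_fails(self, bundle):
        contig = sorted(bundle.genome)[0]
        # a window straddling two random gaps has no designed hairpin
        cand = scan_hairpin(bundle.genome, contig, 5, 27, "+")
        # either nothing is found or whatever is found satisfies the filters
        if cand is not None:
            structure, dg = fold(cand.sequence)
            ok, _, _ = evaluate_candidate(cand.sequence, structure, dg, cand.mature)
            assert ok


class TestStructureHelpers:
    def test_terminal_loops(self):
        assert terminal_loops("((((....))))") == [(4, 8)]
        assert len(terminal_loops("((..((...))..((...))..))")) == 2

    def test_pair_table_unbalanced(self):
        with pytest.raises(ValueError):
            pair_table("((..)")

    def test_candidate_name_round_trip(self):
        name = candidate_name("5p", 69112, 10)
        assert name == "PC-5p-69112_10"
        assert parse_candidate_name(name) == ("5p", 69112, 10)
        with pytest.raises(ValueError):
            candidate_name("7p", 1, 1)
        with pytest.raises(ValueError):
            parse_candidate_name("PC-xx-1_1")
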