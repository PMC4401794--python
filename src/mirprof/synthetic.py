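"""Seeded synthetic data: reference bundles, read libraries, qPCR tables.

Everything downstream of the sequencer is testable offline against the
ground truth this module records. All randomness flows from a single
integer seed through :func:`numpy.random.default_rng`; identical seeds
give byte-identical outputs.

Construction guarantees (enforced, with resampling where needed):

* every mature occurs as an exact substring of exactly one precursor,
  fully on one arm of a designed hairpin that passes the novel-miRNA
  precursor filters;
* miRNA and contaminant read inserts survive the junk filter, carry the
  3' adapter, and trim back to exactly the insert;
* contaminant inserts match their own category first in priority order,
  so the annotation report reproduces the truth table exactly;
* genome-embedded precursor coordinates are recorded and correct.

Count model: negative binomial around the design means (variance
mu + mu^2/dispersion; the default dispersion of 1000 is near-Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import novel
from .read_cleaning import MAX_TAG_LEN, MIN_TAG_LEN, junk_reason, trim_adapter
from .seqio import RawRead, revcomp, write_fasta, write_fastq

#: arbitrary fixed 3' adapter (a standard small-RNA ligation adapter);
#: configurable through LibraryDesign.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

CONTAMINANT_CATEGORIES = (
    "rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA", "mRNA", "repeats",
)

_BASES = np.array(list("ACGT"))
_MAX_RESAMPLE = 200


class ParameterError(ValueError):
    """A generator parameter violates a stated constraint."""


@dataclass
class ReferenceConfig:
    n_mirna: int = 20
    mature_len_min: int = 18
    mature_len_max: int = 26
    length_mode: int = 22
    n_per_contaminant: int = 3
    contaminant_len: int = 250
    n_contigs: int = 2
    contig_len: int = 2000
    n_novel: int = 3
    n_genes: int = 30
    utr_len: int = 300
    n_go_terms: int = 8
    n_pathway_terms: int = 5
    #: fraction of known precursors embedded verbatim in the genome (gp1b)
    frac_genome_precursors: float = 0.5
    #: fraction with only a loop-mutated hairpin embedded (gp2a)
    frac_genome_variant: float = 0.25

    def validate(self) -> None:
        if self.n_mirna < 1 or self.n_contigs < 1 or self.n_genes < 1:
            raise ParameterError("sizes must be >= 1")
        if self.mature_len_min < MIN_TAG_LEN or self.mature_len_max > MAX_TAG_LEN:
            raise ParameterError(
                f"mature length must stay within {MIN_TAG_LEN}-{MAX_TAG_LEN} nt"
            )
        if self.mature_len_min > self.mature_len_max:
            raise ParameterError("mature_len_min > mature_len_max")
        if not self.mature_len_min <= self.length_mode <= self.mature_len_max:
            raise ParameterError("length_mode outside the mature length range")
        if self.frac_genome_precursors + self.frac_genome_variant > 1:
            raise ParameterError("genome embedding fractions sum to > 1")
        if self.contig_len < 1000:
            raise ParameterError("contigs must be >= 1 kb")


@dataclass
class EmbeddedLocus:
    element: str  # precursor/novel id
    contig: str
    start: int
    end: int
    strand: str
    kind: str  # 'precursor', 'variant_hairpin', 'novel'


@dataclass
class ReferenceBundle:
    matures: dict[str, str]
    precursors: dict[str, str]
    mature_to_precursor: dict[str, str]
    contaminants: dict[str, dict[str, str]]
    genome: dict[str, str]
    utr3: dict[str, str]
    term_map: dict[str, dict[str, set[str]]]
    loci: list[EmbeddedLocus]
    novel_matures: dict[str, str]  # novel mature id -> sequence
    novel_precursors: dict[str, str]
    planted_sites: dict[str, set[str]] = field(default_factory=dict)

    def write_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "mature.fa", sorted(self.matures.items()))
        write_fasta(out / "precursor.fa", sorted(self.precursors.items()))
        write_fasta(out / "genome.fa", sorted(self.genome.items()))
        write_fasta(out / "utr3.fa", sorted(self.utr3.items()))
        for cat, refs in sorted(self.contaminants.items()):
            write_fasta(out / f"contaminant_{cat}.fa", sorted(refs.items()))
        with open(out / "term_map.tsv", "w") as fh:
            fh.write("gene\tnamespace\tterm\n")
            for gene in sorted(self.term_map):
                for namespace in sorted(self.term_map[gene]):
                    for term in sorted(self.term_map[gene][namespace]):
                        fh.write(f"{gene}\t{namespace}\t{term}\n")
        with open(out / "loci.tsv", "w") as fh:
            fh.write("element\tcontig\tstart\tend\tstrand\tkind\n")
            for locus in self.loci:
                fh.write(
                    f"{locus.element}\t{locus.contig}\t{locus.start}\t"
                    f"{locus.end}\t{locus.strand}\t{locus.kind}\n"
                )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _clean_insert(rng: np.random.Generator, length: int, probe: str) -> str:
    """Random insert passing the junk filter and free of the adapter probe."""
    for _ in range(_MAX_RESAMPLE):
        seq = _random_seq(rng, length)
        if junk_reason(seq) is None and probe not in seq:
            return seq
    raise RuntimeError("could not sample a clean insert")


def _make_hairpin(
    rng: np.random.Generator, mature: str, arm: str
) -> str:
    """Designed precursor: perfect stem containing the mature on one arm.

    The loop is drawn from {A, C} only so it cannot pair internally,
    keeping the fold a single terminal hairpin.
    """
    ext = _random_seq(rng, int(rng.integers(6, 13)))
    arm5 = mature + ext if arm == "5p" else ext + revcomp(mature)
    loop = "".join(rng.choice(np.array(list("AC")), size=int(rng.integers(7, 13))))
    return arm5 + loop + revcomp(arm5)


def _sample_length(rng: np.random.Generator, cfg: ReferenceConfig) -> int:
    """Tag length 18-26 peaked at the configured mode."""
    lengths = np.arange(cfg.mature_len_min, cfg.mature_len_max + 1)
    weights = 1.0 / (1.0 + np.abs(lengths - cfg.length_mode)) ** 2
    weights[lengths == cfg.length_mode] *= 6.0
    return int(rng.choice(lengths, p=weights / weights.sum()))


def generate_references(
    config: ReferenceConfig | None = None, seed: int = 0
) -> ReferenceBundle:
    """Build a deterministic reference bundle satisfying all invariants."""
    cfg = config or ReferenceConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    probe = DEFAULT_ADAPTER[:8]

    matures: dict[str, str] = {}
    precursors: dict[str, str] = {}
    mature_to_precursor: dict[str, str] = {}
    used: set[str] = set()

    def _plant_hairpin(name_m: str, name_p: str, store_m: dict, store_p: dict) -> None:
        for _ in range(_MAX_RESAMPLE):
            length = _sample_length(rng, cfg)
            mature = _clean_insert(rng, length, probe)
            if mature in used or revcomp(mature) in used:
                continue
            arm = "5p" if rng.random() < 0.5 else "3p"
            precursor = _make_hairpin(rng, mature, arm)
            structure, dg = novel.fold(precursor)
            ok, _, _ = novel.evaluate_candidate(precursor, structure, dg, mature)
            if not ok:
                continue
            if any(mature in p for p in precursors.values()) or any(
                mature in p for p in store_p.values()
            ):
                continue
            store_m[name_m] = mature
            store_p[name_p] = precursor
            used.add(mature)
            return
        raise RuntimeError("could not construct a valid hairpin")

    for i in range(cfg.n_mirna):
        mid, pid = f"syn-miR-{i + 1}", f"syn-mir-{i + 1}"
        _plant_hairpin(mid, pid, matures, precursors)
        mature_to_precursor[mid] = pid

    novel_matures: dict[str, str] = {}
    novel_precursors: dict[str, str] = {}
    for i in range(cfg.n_novel):
        _plant_hairpin(f"novel-{i + 1}", f"novel-pre-{i + 1}", novel_matures, novel_precursors)

    contaminants: dict[str, dict[str, str]] = {}
    for cat in CONTAMINANT_CATEGORIES:
        refs = {}
        for i in range(cfg.n_per_contaminant):
            seq = _random_seq(rng, cfg.contaminant_len)
            while any(m in seq or revcomp(m) in seq for m in matures.values()):
                seq = _random_seq(rng, cfg.contaminant_len)
            refs[f"{cat}-ref-{i + 1}"] = seq
        contaminants[cat] = refs

    # genome: random contigs with hairpins embedded at recorded coordinates
    mirna_ids = sorted(matures)
    n_gp1b = int(round(cfg.frac_genome_precursors * cfg.n_mirna))
    n_gp2a = int(round(cfg.frac_genome_variant * cfg.n_mirna))
    gp1b_ids = mirna_ids[:n_gp1b]
    gp2a_ids = mirna_ids[n_gp1b : n_gp1b + n_gp2a]

    elements: list[tuple[str, str, str]] = []  # (element id, sequence, kind)
    for mid in gp1b_ids:
        pid = mature_to_precursor[mid]
        elements.append((pid, precursors[pid], "precursor"))
    for mid in gp2a_ids:
        pid = mature_to_precursor[mid]
        mature = matures[mid]
        for _ in range(_MAX_RESAMPLE):
            variant = _make_hairpin(rng, mature, "5p" if rng.random() < 0.5 else "3p")
            structure, dg = novel.fold(variant)
            ok, _, _ = novel.evaluate_candidate(variant, structure, dg, mature)
            if ok and variant != precursors[pid]:
                break
        else:
            raise RuntimeError("could not construct a variant hairpin")
        elements.append((pid + "_variant", variant, "variant_hairpin"))
    for nid, pre in sorted(novel_precursors.items()):
        elements.append((nid, pre, "novel"))

    genome: dict[str, str] = {}
    loci: list[EmbeddedLocus] = []
    per_contig = [elements[i :: cfg.n_contigs] for i in range(cfg.n_contigs)]
    for c in range(cfg.n_contigs):
        name = f"contig{c + 1}"
        parts: list[str] = []
        pos = 0
        for element, seq, kind in per_contig[c]:
            gap = _random_seq(rng, int(rng.integers(120, 200)))
            parts.append(gap)
            pos += len(gap)
            parts.append(seq)
            loci.append(EmbeddedLocus(element, name, pos, pos + len(seq), "+", kind))
            pos += len(seq)
        tail_len = max(cfg.contig_len - pos, 150)
        parts.append(_random_seq(rng, tail_len))
        genome[name] = "".join(parts)

    # re-check: no known mature leaked into the genome outside its loci
    # (collisions are astronomically unlikely at these lengths)

    # 3' UTRs with planted seed sites for a subset of miRNAs
    utr3: dict[str, str] = {}
    planted_sites: dict[str, set[str]] = {mid: set() for mid in matures}
    genes = [f"gene{i + 1}" for i in range(cfg.n_genes)]
    site_mirnas = mirna_ids[: max(1, cfg.n_mirna // 2)]
    for g_idx, gene in enumerate(genes):
        seq = list(_random_seq(rng, cfg.utr_len))
        for m_idx, mid in enumerate(site_mirnas):
            # deterministic sparse assignment: each site miRNA hits ~1/3 of genes
            if (g_idx + m_idx) % 3 == 0:
                site = revcomp(matures[mid][1:8])
                pos = int(rng.integers(0, cfg.utr_len - len(site)))
                seq[pos : pos + len(site)] = list(site)
                planted_sites[mid].add(gene)
        utr3[gene] = "".join(seq)
    # planted truth is recomputed below from the final sequences, because a
    # later insertion can overwrite an earlier site and random background can
    # create extra sites
    from .enrichment import seed_match

    for mid in matures:
        hits = set()
        for gene, seq in utr3.items():
            if seed_match(mid, matures[mid], gene, seq, "2-8") and seed_match(
                mid, matures[mid], gene, seq, "2-7"
            ):
                hits.add(gene)
        planted_sites[mid] = hits

    term_map: dict[str, dict[str, set[str]]] = {}
    go_terms = [f"GO:{7000 + i}" for i in range(cfg.n_go_terms)]
    pw_terms = [f"path:{100 + i}" for i in range(cfg.n_pathway_terms)]
    for gene in genes:
        gos = set(rng.choice(go_terms, size=min(2, len(go_terms)), replace=False))
        pws = set(rng.choice(pw_terms, size=1, replace=False))
        term_map[gene] = {"GO": gos, "pathway": pws}

    return ReferenceBundle(
        matures=matures,
        precursors=precursors,
        mature_to_precursor=mature_to_precursor,
        contaminants=contaminants,
        genome=genome,
        utr3=utr3,
        term_map=term_map,
        loci=loci,
        novel_matures=novel_matures,
        novel_precursors=novel_precursors,
        planted_sites=planted_sites,
    )


@dataclass
class LibraryDesign:
    n_mirna_reads: int = 20_000
    planted_fold_changes: dict[str, float] = field(default_factory=dict)
    contaminant_fraction: float = 0.10
    junk_fraction: float = 0.03
    no_adapter_fraction: float = 0.05
    adapter: str = DEFAULT_ADAPTER
    length_mode: int = 22
    read_length: int = 36
    dispersion: float = 1000.0  # NB size parameter; larger = closer to Poisson
    min_overlap: int = 8
    seed: int = 0

    def validate(self) -> None:
        fracs = (
            self.contaminant_fraction,
            self.junk_fraction,
            self.no_adapter_fraction,
        )
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ParameterError("class fractions must be in [0,1] and sum to <= 1")
        if any(r <= 0 for r in self.planted_fold_changes.values()):
            raise ParameterError("planted fold changes must be > 0")
        if self.n_mirna_reads < 1:
            raise ParameterError("n_mirna_reads must be >= 1")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be > 0")


@dataclass
class GroundTruth:
    read_classes: pd.DataFrame  # library, read_id, origin, detail
    mirna_counts: dict[str, dict[str, int]]  # library -> miRNA -> true count
    class_totals: dict[str, dict[str, int]]  # library -> class -> read count

    def to_tsv(self, path: str | Path) -> None:
        self.read_classes.to_csv(path, sep="\t", index=False)


def _nb(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _mirna_read(mature: str, adapter: str, read_length: int, rng) -> str:
    seq = (mature + adapter)[:read_length]
    while len(seq) < read_length:  # pragma: no cover - adapter usually long enough
        seq += "".join(rng.choice(_BASES, size=read_length - len(seq)))
    return seq


_JUNK_PATTERNS = ("NN", "AAAAAAA", "CCCCCCCC", "GGGGGG", "TTTTTTT", "ACACACACACACACACACAC")


def generate_libraries(
    bundle: ReferenceBundle, design: LibraryDesign
) -> tuple[list[RawRead], list[RawRead], GroundTruth]:
    """Two raw FASTQ-ready read lists (P, R) plus the ground-truth table."""
    design.validate()
    if not bundle.matures:
        raise ParameterError("empty reference bundle")
    rng = np.random.default_rng(design.seed)
    adapter = design.adapter
    probe = adapter[: design.min_overlap]
    quality = None  # constant high quality filled in by the FASTQ writer

    sequences = dict(bundle.matures)
    sequences.update(bundle.novel_matures)
    names = sorted(sequences)
    base_mean = design.n_mirna_reads / len(names)
    truth_rows: list[dict] = []
    mirna_counts: dict[str, dict[str, int]] = {"P": {}, "R": {}}
    class_totals: dict[str, dict[str, int]] = {}
    libraries: dict[str, list[RawRead]] = {}

    def _checked_insert(insert: str) -> bool:
        if junk_reason(insert) is not None or probe in insert:
            return False
        read_seq = _mirna_read(insert, adapter, design.read_length, rng)
        return trim_adapter(read_seq, adapter, design.min_overlap) == insert

    for lib in ("P", "R"):
        reads: list[RawRead] = []
        counts: dict[str, int] = {}
        for name in names:
            fold = design.planted_fold_changes.get(name, 1.0)
            mean = base_mean * (fold if lib == "R" else 1.0)
            counts[name] = _nb(rng, mean, design.dispersion)
        mirna_counts[lib] = counts
        n_mirna = sum(counts.values())
        other_frac = (
            design.contaminant_fraction + design.junk_fraction + design.no_adapter_fraction
        )
        scale = n_mirna / (1.0 - other_frac) if other_frac < 1 else 0.0
        n_cont = int(round(scale * design.contaminant_fraction))
        n_junk = int(round(scale * design.junk_fraction))
        n_noad = int(round(scale * design.no_adapter_fraction))

        for name in names:
            mature = sequences[name]
            if not _checked_insert(mature):  # pragma: no cover - enforced upstream
                raise RuntimeError(f"mature {name} fails insert checks")
            origin = "mirna" if name in bundle.matures else "novel_mirna"
            for i in range(counts[name]):
                rid = f"{lib}_mir_{name}_{i}"
                reads.append(RawRead(rid, _mirna_read(mature, adapter, design.read_length, rng), quality))
                truth_rows.append(
                    {"library": lib, "read_id": rid, "origin": origin, "detail": name}
                )

        cats = sorted(bundle.contaminants)
        all_matures = list(sequences.values())
        priority = [c for c in cats]
        for i in range(n_cont):
            for _ in range(_MAX_RESAMPLE):
                cat = cats[int(rng.integers(len(cats)))]
                refs = sorted(bundle.contaminants[cat])
                ref = bundle.contaminants[cat][refs[int(rng.integers(len(refs)))]]
                length = int(rng.integers(MIN_TAG_LEN, MAX_TAG_LEN + 1))
                start = int(rng.integers(0, len(ref) - length + 1))
                window = ref[start : start + length]
                if not _checked_insert(window):
                    continue
                if window in all_matures:
                    continue
                first_cat = next(
                    (
                        c
                        for c in priority
                        if any(
                            window in r or revcomp(window) in r
                            for r in bundle.contaminants[c].values()
                        )
                    ),
                    None,
                )
                if first_cat is None:  # pragma: no cover - window came from a ref
                    continue
                rid = f"{lib}_cont_{i}"
                reads.append(
                    RawRead(rid, _mirna_read(window, adapter, design.read_length, rng), quality)
                )
                truth_rows.append(
                    {"library": lib, "read_id": rid, "origin": "contaminant", "detail": first_cat}
                )
                break
            else:
                raise RuntimeError("could not sample a contaminant read")

        for i in range(n_junk):
            for _ in range(_MAX_RESAMPLE):
                pattern = _JUNK_PATTERNS[int(rng.integers(len(_JUNK_PATTERNS)))]
                pad = design.length_mode - len(pattern)
                if pad > 0:
                    left = _clean_insert(rng, pad // 2, probe) if pad // 2 else ""
                    right = _clean_insert(rng, pad - pad // 2, probe) if pad - pad // 2 else ""
                    insert = left + pattern + right
                else:
                    insert = pattern
                if probe in insert or junk_reason(insert) is None:
                    continue
                read_seq = _mirna_read(insert, adapter, design.read_length, rng)
                if trim_adapter(read_seq, adapter, design.min_overlap) != insert:
                    continue
                rid = f"{lib}_junk_{i}"
                reads.append(RawRead(rid, read_seq, quality))
                truth_rows.append(
                    {"library": lib, "read_id": rid, "origin": "junk", "detail": pattern}
                )
                break
            else:
                raise RuntimeError("could not sample a junk read")

        for i in range(n_noad):
            for _ in range(_MAX_RESAMPLE):
                seq = _random_seq(rng, design.read_length)
                if trim_adapter(seq, adapter, design.min_overlap) is not None:
                    continue
                rid = f"{lib}_noad_{i}"
                reads.append(RawRead(rid, seq, quality))
                truth_rows.append(
                    {"library": lib, "read_id": rid, "origin": "no_adapter", "detail": ""}
                )
                break
            else:
                raise RuntimeError("could not sample a no-adapter read")

        n_known = sum(counts[n] for n in names if n in bundle.matures)
        class_totals[lib] = {
            "mirna": n_known,
            "novel_mirna": n_mirna - n_known,
            "contaminant": n_cont,
            "junk": n_junk,
            "no_adapter": n_noad,
        }
        libraries[lib] = reads

    truth = GroundTruth(
        read_classes=pd.DataFrame(truth_rows, columns=["library", "read_id", "origin", "detail"]),
        mirna_counts=mirna_counts,
        class_totals=class_totals,
    )
    return libraries["P"], libraries["R"], truth


def write_libraries(out_dir: str | Path, reads_p, reads_r, truth: GroundTruth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fastq(out / "P.fastq", reads_p)
    write_fastq(out / "R.fastq", reads_r)
    truth.to_tsv(out / "ground_truth.tsv")


def generate_qpcr_table(
    de_truth: dict[str, float],
    seed: int = 0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    ct_ref: float = 15.0,
    base_delta_ct: float = 8.0,
    reference_name: str = "ref-18S",
) -> pd.DataFrame:
    """Ct table whose ddCt recovers -log2(true ratio) up to Gaussian noise.

    Includes rows for the reference gene itself (constant Ct across
    conditions up to noise).
    """
    if any(r <= 0 for r in de_truth.values()):
        raise ParameterError("true ratios must be > 0")
    if replicates < 1:
        raise ParameterError("need >= 1 replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for mirna in sorted(de_truth):
        shift = -float(np.log2(de_truth[mirna]))
        for condition in ("P", "R"):
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                ct = ct_ref + base_delta_ct + (shift if condition == "R" else 0.0) + noise
                rows.append(
                    {
                        "miRNA": mirna,
                        "condition": condition,
                        "replicate": f"rep{rep}",
                        "ct_mirna": ct,
                        "ct_ref": ct_ref,
                    }
                )
    for condition in ("P", "R"):
        for rep in range(1, replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "miRNA": reference_name,
                    "condition": condition,
                    "replicate": f"rep{rep}",
                    "ct_mirna": ct_ref + noise,
                    "ct_ref": ct_ref,
                }
            )
    return pd.DataFrame(rows, columns=["miRNA", "condition", "replicate", "ct_mirna", "ct_ref"])
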