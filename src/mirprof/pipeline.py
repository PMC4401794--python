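"""End-to-end orchestration: cleaning -> annotation -> known/novel ->
DE -> targets/enrichment/network -> qPCR, with a run manifest.

Inputs come from a single config mapping (YAML on the CLI); a rerun with
the same config and inputs is byte-identical (no timestamps in outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__, diffexpr, enrichment, known, novel, qpcr
from .annotation import DEFAULT_PRIORITY, classify_tags, write_annotation_tsv
from .read_cleaning import clean_library, write_report_tsv, write_tags_fasta
from .seqio import read_raw, read_sequences, revcomp
from .synthetic import DEFAULT_ADAPTER

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_CONFIG = {
    "adapter": DEFAULT_ADAPTER,
    "min_overlap": 8,
    "max_mismatch": 1,
    "max_offset": 3,
    "alpha": 0.05,
    "min_ne": 1.0,
    "zero_replacement": 0.001,
    "flank": 80,
    "seed": 0,
    "target_mode": "strict",
    "network_weights": "log2",
    "stages": {"novel": True, "enrichment": True, "qpcr": True},
}


def load_term_map(path) -> dict[str, dict[str, set[str]]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, set[str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene, {}).setdefault(row.namespace, set()).add(row.term)
    return out


def _config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def venn_summary(set_r: set, set_p: set) -> tuple[int, int, int, int]:
    """(|R|, |P|, |R&P|, |R|P union|) for two detected-name sets."""
    inter = len(set_r & set_p)
    return len(set_r), len(set_p), inter, len(set_r) + len(set_p) - inter


def _find_locus(genome: Mapping[str, str], seq: str):
    """First exact genome locus of a sequence (plus then minus strand)."""
    for contig in sorted(genome):
        pos = genome[contig].find(seq)
        if pos != -1:
            return contig, pos, pos + len(seq), "+"
    rc = revcomp(seq)
    for contig in sorted(genome):
        pos = genome[contig].find(rc)
        if pos != -1:
            return contig, pos, pos + len(seq), "-"
    return None


def _length_distribution(tag_sets: dict[str, list]) -> pd.DataFrame:
    rows = []
    for lib, tags in tag_sets.items():
        counts: Counter[int] = Counter()
        for tag in tags:
            counts[len(tag.sequence)] += tag.count
        total = sum(counts.values())
        for length in sorted(counts):
            rows.append(
                {
                    "library": lib,
                    "length": length,
                    "count": counts[length],
                    "pct": round(100.0 * counts[length] / total, 2) if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["library", "length", "count", "pct"])


def run_pipeline(config: Mapping, out_dir: str | Path) -> Path:
    """Run every enabled stage; returns the run directory."""
    cfg = dict(DEFAULT_CONFIG)
    stages = dict(DEFAULT_CONFIG["stages"])
    user = dict(config)
    stages.update(user.pop("stages", {}))
    cfg.update(user)
    cfg["stages"] = stages

    for key in ("reads_p", "reads_r", "refs_dir"):
        if key not in cfg:
            raise ConfigError(f"config missing required key {key!r}")
        if not Path(cfg[key]).exists():
            raise ConfigError(f"{key} path does not exist: {cfg[key]}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs_dir = Path(cfg["refs_dir"])

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("load_references")
        matures = read_sequences(refs_dir / "mature.fa")
        precursors = read_sequences(refs_dir / "precursor.fa")
        genome = read_sequences(refs_dir / "genome.fa")
        utrs = read_sequences(refs_dir / "utr3.fa")
        contaminants = {}
        for path in sorted(refs_dir.glob("contaminant_*.fa")):
            category = path.stem.removeprefix("contaminant_")
            contaminants[category] = read_sequences(path)
        term_map_path = refs_dir / "term_map.tsv"
        term_map = load_term_map(term_map_path) if term_map_path.exists() else {}
    except ConfigError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("load_references", exc) from exc

    # --- cleaning -------------------------------------------------------
    tag_sets: dict[str, list] = {}
    reports = {}
    try:
        for lib, key in (("P", "reads_p"), ("R", "reads_r")):
            tags, report = clean_library(
                read_raw(cfg[key]), cfg["adapter"], cfg["min_overlap"]
            )
            tag_sets[lib] = tags
            reports[lib] = report
            write_report_tsv(out / f"cleaning_report_{lib}.tsv", report)
            write_tags_fasta(out / f"tags_{lib}.fa", tags)
            logger.info(
                "clean %s: raw=%d clean=%d", lib, report.raw_total, report.clean_total
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("cleaning", exc) from exc

    # --- annotation -----------------------------------------------------
    retained = {}
    try:
        priority = [c for c in DEFAULT_PRIORITY if c in contaminants]
        for lib in ("P", "R"):
            kept, ann_report, _ = classify_tags(
                tag_sets[lib],
                contaminants,
                priority=priority,
                max_mismatch=0,
                raw_total=reports[lib].raw_total,
            )
            retained[lib] = kept
            write_annotation_tsv(out / f"annotation_report_{lib}.tsv", ann_report)
            logger.info("annotate %s: retained=%d tags", lib, len(kept))
        # "clean reads" for normalization = retained after contaminant removal
        clean_totals = {
            lib: sum(t.count for t in retained[lib]) for lib in ("P", "R")
        }
        _length_distribution(retained).to_csv(
            out / "length_distribution.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("annotation", exc) from exc

    # --- known miRNAs ---------------------------------------------------
    try:
        hairpin_cache: dict[str, bool] = {}

        def hairpin_check(seq: str) -> bool:
            if seq not in hairpin_cache:
                locus = _find_locus(genome, seq)
                hairpin_cache[seq] = bool(
                    locus
                    and novel.scan_hairpin(
                        genome, locus[0], locus[1], locus[2], locus[3], cfg["flank"]
                    )
                )
            return hairpin_cache[seq]

        ctx = known.GroupContext(genome, precursors, hairpin_check)
        records, detected, unmatched = known.identify_known(
            [retained["P"], retained["R"]],
            matures,
            precursors,
            ctx,
            cfg["max_mismatch"],
            cfg["max_offset"],
        )
        known_df = pd.DataFrame(
            [
                {
                    "miRNA": r.name,
                    "group": r.group,
                    "count_P": r.counts[0],
                    "count_R": r.counts[1],
                }
                for r in records
            ],
            columns=["miRNA", "group", "count_P", "count_R"],
        )
        known_df.to_csv(out / "known_mirnas.tsv", sep="\t", index=False)
        group_counts = known_df.groupby("group")["miRNA"].count().rename("n_mirnas")
        group_counts.to_csv(out / "group_counts.tsv", sep="\t")
        logger.info("known: %d variants", len(records))
    except Exception as exc:  # noqa: BLE001
        raise StageError("known_mirna", exc) from exc

    # --- novel miRNAs ---------------------------------------------------
    novel_rows: list[dict] = []
    novel_counts: dict[str, dict[str, int]] = {"P": {}, "R": {}}
    novel_seqs: dict[str, str] = {}
    if cfg["stages"].get("novel", True):
        try:
            per_seq: dict[str, dict[str, int]] = {}
            for lib in ("P", "R"):
                for tag in unmatched[str(0 if lib == "P" else 1)]:
                    per_seq.setdefault(tag.sequence, {"P": 0, "R": 0})[lib] += tag.count
            index = 0
            bed_lines = []
            for seq in sorted(per_seq, key=lambda s: (-sum(per_seq[s].values()), s)):
                locus = _find_locus(genome, seq)
                if locus is None:
                    continue
                cand = novel.scan_hairpin(
                    genome, locus[0], locus[1], locus[2], locus[3], cfg["flank"]
                )
                if cand is None:
                    continue
                index += 1
                total = sum(per_seq[seq].values())
                name = novel.candidate_name(cand.arm, index, total)
                novel_seqs[name] = seq
                for lib in ("P", "R"):
                    if per_seq[seq][lib]:
                        novel_counts[lib][name] = per_seq[seq][lib]
                novel_rows.append(
                    {
                        "name": name,
                        "length": len(seq),
                        "precursor_length": len(cand.sequence),
                        "structure": cand.structure,
                        "dG": cand.dg,
                        "gc": round(cand.gc_fraction, 3),
                        "count_P": per_seq[seq]["P"],
                        "count_R": per_seq[seq]["R"],
                        "NE_P": round(
                            diffexpr.normalize(per_seq[seq]["P"], clean_totals["P"]), 2
                        ),
                        "NE_R": round(
                            diffexpr.normalize(per_seq[seq]["R"], clean_totals["R"]), 2
                        ),
                    }
                )
                bed_lines.append(
                    f"{cand.contig}\t{cand.start}\t{cand.end}\t{name}\t0\t{cand.strand}"
                )
            pd.DataFrame(
                novel_rows,
                columns=[
                    "name", "length", "precursor_length", "structure", "dG", "gc",
                    "count_P", "count_R", "NE_P", "NE_R",
                ],
            ).to_csv(out / "novel_mirnas.tsv", sep="\t", index=False)
            (out / "novel_mirnas.bed").write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))
            logger.info("novel: %d candidates", len(novel_rows))
        except Exception as exc:  # noqa: BLE001
            raise StageError("novel_mirna", exc) from exc

    # --- venn -----------------------------------------------------------
    set_r = set(detected[1]) | {n for n, c in novel_counts["R"].items() if c > 0}
    set_p = set(detected[0]) | {n for n, c in novel_counts["P"].items() if c > 0}
    n_r, n_p, n_both, n_union = venn_summary(set_r, set_p)
    pd.DataFrame(
        [{"R": n_r, "P": n_p, "shared": n_both, "union": n_union}]
    ).to_csv(out / "venn.tsv", sep="\t", index=False)

    # --- differential expression ---------------------------------------
    try:
        counts_p = {r.name: r.counts[0] for r in records}
        counts_r = {r.name: r.counts[1] for r in records}
        counts_p.update(novel_counts["P"])
        counts_r.update(novel_counts["R"])
        results = diffexpr.de_table(
            counts_p,
            counts_r,
            clean_totals["P"],
            clean_totals["R"],
            alpha=cfg["alpha"],
            min_ne=cfg["min_ne"],
            zero_replacement=cfg["zero_replacement"],
        )
        de_df = diffexpr.de_frame(results)
        de_df.to_csv(out / "de_table.tsv", sep="\t", index=False)
        logger.info(
            "de: %d tested, %d significant",
            len(results),
            sum(r.significant for r in results),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("diff_expression", exc) from exc

    # --- targets / enrichment / network --------------------------------
    if cfg["stages"].get("enrichment", True) and utrs:
        try:
            name_to_seq: dict[str, str] = dict(novel_seqs)
            for r in records:
                base, _, _, _ = known.parse_variant_name(r.name)
                name_to_seq.setdefault(r.name, matures.get(base, ""))
            # recover the tag sequence for variant names via the match itself
            sig = [r for r in results if r.significant]
            sig_seqs = {
                r.name: name_to_seq.get(r.name, "")
                for r in sig
                if len(name_to_seq.get(r.name, "")) >= 8
            }
            target_map = enrichment.predict_targets(sig_seqs, utrs, cfg["target_mode"])
            target_genes = sorted({g for gs in target_map.values() for g in gs})
            weights = {r.name: r.log2_ratio or 0.0 for r in sig}
            net = enrichment.build_network(weights, target_map, cfg["network_weights"])
            enrichment.edge_list(net).to_csv(out / "network_edges.tsv", sep="\t", index=False)
            pd.DataFrame(net.matrix, index=net.mirnas, columns=net.genes).to_csv(
                out / "network_adjacency.tsv", sep="\t"
            )
            for namespace, fname in (("GO", "enrichment_go.tsv"), ("pathway", "enrichment_pathway.tsv")):
                if term_map and any(namespace in v for v in term_map.values()):
                    terms = enrichment.enrich_terms(target_genes, term_map, namespace, cfg["alpha"])
                    enrichment.enrichment_frame(terms).to_csv(out / fname, sep="\t", index=False)
            logger.info("enrichment: %d target genes", len(target_genes))
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrichment_network", exc) from exc

    # --- qPCR validation ------------------------------------------------
    if cfg["stages"].get("qpcr", True) and cfg.get("ct_table"):
        try:
            ct = qpcr.read_ct_table(cfg["ct_table"])
            ratios = {r.name: r.ratio for r in results if r.ratio is not None}
            qpcr.summarize_validation(ct, ratios).to_csv(
                out / "qpcr_validation.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("qpcr_validation", exc) from exc

    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "parameters_hash": _config_hash(cfg),
        "config": {k: str(v) for k, v in sorted(cfg.items())},
        "counts": {
            "raw_P": reports["P"].raw_total,
            "raw_R": reports["R"].raw_total,
            "clean_P": reports["P"].clean_total,
            "clean_R": reports["R"].clean_total,
            "known_mirnas": len(records),
            "novel_candidates": len(novel_rows),
            "venn_union": n_union,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
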