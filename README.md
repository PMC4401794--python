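# mirprof

Small RNA-seq miRNA profiling for a two-condition comparison, end to end:

- **read cleaning** — 3' adapter trimming, 18–26 nt length filter, junk
  filter (N count, homopolymer runs, tandem di/tri/tetramer repeats),
  collapse to unique tags with counts and a per-fate accounting report;
- **annotation** — contaminant classification (rRNA, tRNA, snRNA, snoRNA,
  other ncRNA, mRNA, repeats) by ungapped full-tag matching on both
  strands with a configurable category priority;
- **known miRNAs** — ≤1-mismatch matching against mature/precursor
  references with isomiR end offsets, canonical variant names
  (`base_L+1R-1`, `base_R+1_1ss12TA`), and gp1b/gp2a/gp3a/gp4a evidence
  groups based on genome mapping and hairpin-forming extensions;
- **novel miRNAs** — 80-nt flank windows around unannotated tag loci,
  secondary-structure folding (built-in weighted-base-pair dynamic
  program; pluggable backend), and precursor filters (length 50–123 nt,
  GC 23–77 %, dG −80.5…−17.7 kcal/mol, single terminal loop, mature on
  one arm);
- **differential expression** — reads-per-million normalization, zero
  (→0.001) and low-expression (NE<1 in both) rules, an exact two-library
  conditional count test with one- and two-sided tails, fold-change
  classes (down ≤0.5 < mid ≤ 2 < up), and single-library "specific"
  flags;
- **targets/enrichment/network** — seed-match target prediction
  (positions 2–7 / 2–8), upper-tail hypergeometric GO/pathway
  enrichment, and a bipartite miRNA–gene adjacency with degrees;
- **qPCR validation** — 2^−ΔΔCt relative expression and direction
  concordance with the sequencing calls;
- **synthetic data** — a seeded generator for reference bundles, raw
  FASTQ libraries with planted fold changes and ground truth, and Ct
  tables, so the whole pipeline is testable offline.

## CLI

All commands are under a single entry point:

```sh
mirprof synth refs  --seed 1 --out-dir refs/
mirprof synth reads --seed 2 --refs-dir refs/ --out-dir reads/
mirprof synth qpcr  --seed 3 --out-dir qpcr/
mirprof clean --adapter TGGAATTCTCGGGTGCCAAGG --min-overlap 8 \
              --in reads/R.fastq --out-prefix R
mirprof de --counts-p p.tsv --counts-r r.tsv --total-p 1000000 \
           --total-r 1200000 --alpha 0.05 --out de.tsv
mirprof enrich --targets genes.txt --term-map refs/term_map.tsv \
               --namespace GO --out go.tsv
mirprof qpcr --ct-table qpcr/ct_table.tsv --baseline P --out qpcr.tsv
mirprof pipeline run --config run.yaml --seed 1 --out run/
```

A minimal pipeline config:

```yaml
reads_p: reads/P.fastq
reads_r: reads/R.fastq
refs_dir: refs/
ct_table: qpcr/ct_table.tsv   # optional
alpha: 0.05
```

The run directory contains the cleaning/annotation reports, length
distribution, known/novel miRNA tables (TSV + BED), the DE table,
enrichment tables, the network edge list and adjacency matrix, the qPCR
summary, and a `manifest.json` (version, seed, parameter hash). Reruns
with the same config and inputs are byte-identical.

## Notes

- The exact test runs on raw counts (the factorials in the conditional
  distribution require integers); normalized expression is used for
  fold changes and the prefilter. One-sided tails are available via
  `diffexpr.ac_tails`; the reported p-value is `min(1, 2·min(C, D))`.
- The built-in folder maximizes weighted base pairs (GC=3, AU=2, GU=1,
  minimum loop 3) and reports `dG = −0.5 × score` kcal/mol. Any
  callable `seq -> (dot_bracket, dG)` can replace it (e.g. a
  thermodynamic folder) via the `backend` argument.
- Target prediction's "strict" mode requires both the 2–7 and 2–8 seed
  matches in a UTR; "loose" accepts either.
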