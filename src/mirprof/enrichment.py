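"""Seed-match target prediction, hypergeometric enrichment, network build.

Target prediction uses the miRNA seed (positions 2-7 or 2-8, 1-based
from the 5' end): a site is an exact occurrence of the seed's reverse
complement in a 3'UTR. "strict" mode requires both seed spans to hit a
UTR (standing in for a two-program intersection), "loose" either.

Enrichment: p = 1 - sum_{i<m} C(M,i) C(N-M,n-i) / C(N,n), the upper-tail
hypergeometric probability, evaluated through the survival function of
:class:`scipy.stats.hypergeom` (log-space internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .seqio import revcomp

logger = logging.getLogger(__name__)

SEED_SPANS = {"2-7": (1, 7), "2-8": (1, 8)}


@dataclass(frozen=True)
class TargetSite:
    mirna: str
    gene: str
    position: int  # 0-based on the UTR
    seed_span: str  # '2-7' or '2-8'


def seed_match(
    mirna_name: str,
    mirna_seq: str,
    gene: str,
    utr_seq: str,
    seed_span: str = "2-7",
) -> list[TargetSite]:
    """All exact seed-complement sites of one miRNA in one UTR."""
    if seed_span not in SEED_SPANS:
        raise ValueError(f"seed_span must be one of {sorted(SEED_SPANS)}")
    seq = mirna_seq.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    lo, hi = SEED_SPANS[seed_span]
    site_seq = revcomp(seq[lo:hi])
    utr = utr_seq.upper().replace("U", "T")
    sites = []
    pos = utr.find(site_seq)
    while pos != -1:
        sites.append(TargetSite(mirna_name, gene, pos, seed_span))
        pos = utr.find(site_seq, pos + 1)
    return sites


def predict_targets(
    mirna_seqs: Mapping[str, str],
    utrs: Mapping[str, str],
    mode: str = "strict",
) -> dict[str, set[str]]:
    """miRNA -> target gene set. strict = both seed spans, loose = either.

    miRNAs without a usable sequence are skipped with a warning.
    """
    if mode not in ("strict", "loose"):
        raise ValueError("mode must be 'strict' or 'loose'")
    out: dict[str, set[str]] = {}
    for name in sorted(mirna_seqs):
        seq = mirna_seqs[name]
        if not seq or len(seq) < 8:
            logger.warning("skipping miRNA %s: no usable sequence", name)
            continue
        genes: set[str] = set()
        for gene in sorted(utrs):
            has = {
                span: bool(seed_match(name, seq, gene, utrs[gene], span))
                for span in SEED_SPANS
            }
            hit = all(has.values()) if mode == "strict" else any(has.values())
            if hit:
                genes.add(gene)
        out[name] = genes
    return out


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for one term: background N/M, target-side n/m."""

    N: int  # annotated genes in background
    n: int  # annotated genes among targets
    M: int  # background genes carrying the term
    m: int  # target genes carrying the term

    def __post_init__(self) -> None:
        if not (0 <= self.m <= min(self.n, self.M) and self.n <= self.N and self.M <= self.N):
            raise ValueError(f"invalid enrichment counts: {self}")


def hypergeom_enrich(inp: EnrichmentInput) -> float:
    """Upper-tail probability of drawing >= m term-carrying genes."""
    if inp.m == 0:
        return 1.0
    return float(np.clip(hypergeom.sf(inp.m - 1, inp.N, inp.M, inp.n), 0.0, 1.0))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    N: int
    n: int
    M: int
    m: int
    p_value: float
    significant: bool


def enrich_terms(
    target_genes: Iterable[str],
    term_map: Mapping[str, Mapping[str, set[str]]],
    namespace: str,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term hit by >= 1 target gene.

    ``term_map`` maps gene -> namespace -> set of terms; the background
    is every gene annotated in the namespace. Results sorted by
    ascending p, ties by term id.
    """
    background = {
        gene for gene, spaces in term_map.items() if spaces.get(namespace)
    }
    if not background:
        raise ValueError(f"no background genes annotated in namespace {namespace!r}")
    targets = set(target_genes) & background
    term_background: dict[str, set[str]] = {}
    for gene in background:
        for term in term_map[gene][namespace]:
            term_background.setdefault(term, set()).add(gene)

    N, n = len(background), len(targets)
    results = []
    for term, genes in term_background.items():
        m = len(genes & targets)
        if m == 0:
            continue
        p = hypergeom_enrich(EnrichmentInput(N, n, len(genes), m))
        results.append(EnrichmentResult(term, N, n, len(genes), m, p, p < alpha))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


@dataclass
class NetworkAdjacency:
    mirnas: list[str]
    genes: list[str]
    matrix: np.ndarray  # shape (len(mirnas), len(genes)), weights >= 0

    def gene_degree(self, gene: str) -> int:
        j = self.genes.index(gene)
        return int((self.matrix[:, j] > 0).sum())

    def mirna_degree(self, mirna: str) -> int:
        i = self.mirnas.index(mirna)
        return int((self.matrix[i, :] > 0).sum())


def build_network(
    mirna_weights: Mapping[str, float],
    target_map: Mapping[str, set[str]],
    weights: str = "log2",
) -> NetworkAdjacency:
    """Bipartite miRNA-gene adjacency from a target map.

    Edge weight is |log2 ratio| of the miRNA (``weights='log2'``) or 1
    (``weights='binary'``); a[i,j] > 0 iff gene j is a target of miRNA i.
    """
    if weights not in ("log2", "binary"):
        raise ValueError("weights must be 'log2' or 'binary'")
    mirnas = sorted(target_map)
    genes = sorted({g for gs in target_map.values() for g in gs})
    matrix = np.zeros((len(mirnas), len(genes)))
    gene_idx = {g: j for j, g in enumerate(genes)}
    for i, mirna in enumerate(mirnas):
        w = 1.0 if weights == "binary" else abs(mirna_weights.get(mirna, 0.0))
        if w == 0.0:
            w = 1.0  # guarantee a[i,j] > 0 for every predicted edge
        for gene in target_map[mirna]:
            matrix[i, gene_idx[gene]] = w
    return NetworkAdjacency(mirnas, genes, matrix)


def edge_list(network: NetworkAdjacency) -> pd.DataFrame:
    rows = [
        {"miRNA": m, "gene": g, "weight": network.matrix[i, j]}
        for i, m in enumerate(network.mirnas)
        for j, g in enumerate(network.genes)
        if network.matrix[i, j] > 0
    ]
    return pd.DataFrame(rows, columns=["miRNA", "gene", "weight"])


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "N": r.N, "n": r.n, "M": r.M, "m": r.m,
                "p_value": r.p_value, "significant": r.significant,
            }
            for r in results
        ],
        columns=["term", "N", "n", "M", "m", "p_value", "significant"],
    )
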