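import itertools

import numpy as np
import pytest

from mirprof.enrichment import (
    EnrichmentInput,
    EnrichmentResult,
    build_network,
    edge_list,
    enrich_terms,
    hypergeom_enrich,
    predict_targets,
    seed_match,
)
from mirprof.seqio import revcomp

MIR34A = "TGGCAGTGTCTTAGCTGGTTGT"


def enumerate_enrich(N: int, n: int, M: int, m: int) -> float:
    """Oracle: exhaustive enumeration of all n-subsets of N genes."""
    hits = sum(
        1
        for subset in itertools.combinations(range(N), n)
        if sum(1 for g in subset if g < M) >= m
    )
    from math import comb

    return hits / comb(N, n)


class TestSeedMatch:
    def test_single_site(self):
        # seed 2-7 of the miRNA is GGCAGT; its reverse complement ACTGCC
        utr = "TTTTT" + "ACTGCC" + "GGGGG"
        sites = seed_match("mir", MIR34A, "g1", utr, "2-7")
        assert len(sites) == 1
        assert sites[0].position == 5
        assert utr[5:11] == revcomp(MIR34A[1:7])

    def test_no_site(self):
        assert seed_match("mir", MIR34A, "g1", "A" * 50, "2-7") == []

    def test_two_sites(self):
        utr = "ACTGCC" + "T" * 10 + "ACTGCC"
        sites = seed_match("mir", MIR34A, "g1", utr, "2-7")
        assert [s.position for s in sites] == [0, 16]

    def test_u_insensitive(self):
        utr = "ACUGCC".replace("U", "U") + "AAAA"
        assert seed_match("mir", MIR34A.replace("T", "U"), "g1", utr, "2-7")

    def test_short_mirna_error(self):
        with pytest.raises(ValueError):
            seed_match("mir", "ACGTACG", "g1", "ACGT", "2-7")

    def test_bad_span_error(self):
        with pytest.raises(ValueError):
            seed_match("mir", MIR34A, "g1", "ACGT", "2-9")


class TestPredictTargets:
    def test_planted_sites_recovered_strict(self, bundle):
        targets = predict_targets(bundle.matures, bundle.utr3, "strict")
        for mid, expected in bundle.planted_sites.items():
            assert targets[mid] == expected, mid

    def test_strict_subset_of_loose(self, bundle):
        strict = predict_targets(bundle.matures, bundle.utr3, "strict")
        loose = predict_targets(bundle.matures, bundle.utr3, "loose")
        for mid in strict:
            assert strict[mid] <= loose[mid]

    def test_unusable_sequence_skipped(self, bundle):
        targets = predict_targets({"bad": "ACG"}, bundle.utr3)
        assert "bad" not in targets

    def test_invalid_mode(self, bundle):
        with pytest.raises(ValueError):
            predict_targets(bundle.matures, bundle.utr3, "both")


class TestHypergeomEnrich:
    def test_worked_example(self):
        # all 4 annotated genes drawn in a sample of 5 from 10: 6/252
        p = hypergeom_enrich(EnrichmentInput(N=10, n=5, M=4, m=4))
        assert p == pytest.approx(6 / 252, abs=1e-12)
        assert p == pytest.approx(enumerate_enrich(10, 5, 4, 4), abs=1e-12)

    def test_m_zero_is_one(self):
        assert hypergeom_enrich(EnrichmentInput(N=10, n=5, M=4, m=0)) == 1.0

    def test_all_background_annotated(self):
        for m in range(1, 6):
            assert hypergeom_enrich(
                EnrichmentInput(N=10, n=5, M=10, m=m)
            ) == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_small_grid(self):
        for N in (5, 8):
            for n in range(N + 1):
                for M in range(N + 1):
                    for m in range(min(n, M) + 1):
                        p = hypergeom_enrich(EnrichmentInput(N, n, M, m))
                        assert p == pytest.approx(
                            enumerate_enrich(N, n, M, m), abs=1e-12
                        ), (N, n, M, m)

    def test_monotone_in_m(self):
        prev = 1.1
        for m in range(0, 6):
            p = hypergeom_enrich(EnrichmentInput(N=20, n=8, M=6, m=min(m, 6)))
            assert p <= prev + 1e-12
            prev = p

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            EnrichmentInput(N=10, n=5, M=4, m=5)
        with pytest.raises(ValueError):
            EnrichmentInput(N=10, n=11, M=4, m=2)


class TestEnrichTerms:
    def _term_map(self):
        # 100 genes; term T given to 10 background genes
        term_map = {}
        for i in range(100):
            terms = {"base"}
            if i < 10:
                terms.add("T")
            term_map[f"g{i}"] = {"GO": terms}
        return term_map

    def test_planted_enrichment_ranks_first(self):
        term_map = self._term_map()
        targets = [f"g{i}" for i in range(9)] + ["g50"]  # 90% carry T
        results = enrich_terms(targets, term_map, "GO")
        assert results[0].term == "T"
        assert results[0].p_value < 0.05
        assert results[0].significant

    def test_universal_term_p_one(self):
        term_map = {f"g{i}": {"GO": {"everything"}} for i in range(30)}
        results = enrich_terms([f"g{i}" for i in range(5)], term_map, "GO")
        assert results[0].p_value == pytest.approx(1.0)
        assert not results[0].significant

    def test_type_one_error_rate(self):
        term_map = self._term_map()
        rng = np.random.default_rng(0)
        false_hits = trials = 0
        for _ in range(20):
            targets = rng.choice([f"g{i}" for i in range(100)], size=20, replace=False)
            for res in enrich_terms(targets.tolist(), term_map, "GO"):
                if res.term == "T":
                    trials += 1
                    false_hits += res.significant
        assert false_hits / max(trials, 1) < 0.3  # crude null check, small sample

    def test_empty_background_error(self):
        with pytest.raises(ValueError):
            enrich_terms(["g1"], {"g1": {"GO": set()}}, "GO")

    def test_counts_recorded(self):
        term_map = self._term_map()
        results = enrich_terms([f"g{i}" for i in range(5)], term_map, "GO")
        by_term = {r.term: r for r in results}
        assert by_term["T"].N == 100 and by_term["T"].n == 5
        assert by_term["T"].M == 10 and by_term["T"].m == 5


class TestNetwork:
    def test_shared_gene_degree(self):
        net = build_network(
            {"m1": 2.0, "m2": -1.5},
            {"m1": {"gA"}, "m2": {"gA"}},
        )
        assert net.gene_degree("gA") == 2

    def test_empty_targets_zero_matrix(self):
        net = build_network({"m1": 2.0}, {"m1": set()})
        assert net.matrix.size == 0 or (net.matrix == 0).all()

    def test_hub_gene_top_ranked(self):
        target_map = {f"m{i}": {"hub"} | {f"g{i}"} for i in range(8)}
        weights = {f"m{i}": 1.0 for i in range(8)}
        net = build_network(weights, target_map)
        degrees = {g: net.gene_degree(g) for g in net.genes}
        assert degrees["hub"] == 8
        assert max(degrees, key=degrees.get) == "hub"

    def test_edge_weights_log2(self):
        net = build_network({"m1": -2.5}, {"m1": {"gA"}}, weights="log2")
        assert net.matrix[0, 0] == pytest.approx(2.5)
        binary = build_network({"m1": -2.5}, {"m1": {"gA"}}, weights="binary")
        assert binary.matrix[0, 0] == 1.0

    def test_edge_list(self):
        net = build_network({"m1": 1.0}, {"m1": {"gA", "gB"}})
        df = edge_list(net)
        assert set(df["gene"]) == {"gA", "gB"}
        assert (df["weight"] > 0).all()

    def test_positive_entries_iff_target(self):
        net = build_network(
            {"m1": 0.0, "m2": 3.0},
            {"m1": {"gA"}, "m2": {"gB"}},
        )
        for i, m in enumerate(net.mirnas):
            for j, g in enumerate(net.genes):
                expected = g in {"m1": {"gA"}, "m2": {"gB"}}[m]
                assert (net.matrix[i, j] > 0) == expected
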