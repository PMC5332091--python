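"""Promoter extraction, IUPAC scanning, and binomial enrichment."""

from math import comb

import numpy as np
import pytest

from hdzipkit.cisreg import (CatalogEntry, ElementHit, default_catalog,
                             enrichment_test, exact_binom_upper,
                             extract_promoter, is_palindromic, revcomp,
                             scan_elements, validate_catalog)
from hdzipkit.genestruct import GeneModel


def _gene(chrom="chr1", strand="+", start=2_000, end=3_000):
    return GeneModel("g", chrom, strand, start, end, [(start, end)],
                     start if strand == "+" else end)


class TestExtractPromoter:
    GENOME = {"chr1": "".join(
        np.random.default_rng(1).choice(list("ACGT"), 10_000))}

    def test_plus_strand_window(self):
        prom, truncated = extract_promoter(self.GENOME, _gene())
        assert not truncated
        assert prom == self.GENOME["chr1"][500:2_000]

    def test_minus_strand_revcomp_involution(self):
        gene = _gene(strand="-")
        prom, _ = extract_promoter(self.GENOME, gene)
        assert revcomp(prom) == self.GENOME["chr1"][3_000:4_500]

    def test_truncated_at_contig_edge(self):
        prom, truncated = extract_promoter(self.GENOME, _gene(start=800,
                                                              end=900))
        assert truncated and len(prom) == 800

    def test_missing_chromosome(self):
        with pytest.raises(KeyError):
            extract_promoter(self.GENOME, _gene(chrom="chrZ"))


class TestScanElements:
    def test_promoter_equal_to_pattern(self):
        cat = [CatalogEntry("X", "CAACTG", "test")]
        hits = scan_elements("g", "CAACTG", cat, both_strands=False)
        assert len(hits) == 1 and hits[0].offset == 0

    def test_overlapping_occurrences_all_reported(self):
        cat = [CatalogEntry("X", "AAA", "test")]
        hits = scan_elements("g", "AAAAA", cat, both_strands=False)
        assert [h.offset for h in hits] == [0, 1, 2]

    def test_palindrome_deduplicated_when_requested(self):
        cat = [CatalogEntry("G-box", "CACGTG", "light")]
        assert is_palindromic("CACGTG")
        both = scan_elements("g", "TTCACGTGTT", cat, both_strands=True,
                             dedupe_palindromes=False)
        deduped = scan_elements("g", "TTCACGTGTT", cat, both_strands=True,
                                dedupe_palindromes=True)
        assert len(both) == 2 and len(deduped) == 1
        assert {h.offset for h in both} == {2}

    def test_case_insensitive(self):
        cat = [CatalogEntry("X", "CAACTG", "test")]
        assert scan_elements("g", "caactg", cat) == \
            scan_elements("g", "CAACTG", cat)

    def test_sequence_n_never_matches(self):
        cat = [CatalogEntry("X", "CANCTG", "test")]  # pattern N = any base
        assert scan_elements("g", "CANCTG", cat, both_strands=False) == []
        assert len(scan_elements("g", "CAGCTG", cat,
                                 both_strands=False)) == 1

    def test_invalid_iupac_code_names_entry(self):
        with pytest.raises(ValueError, match="BAD"):
            validate_catalog([CatalogEntry("BAD", "ACZ", "test")])

    def test_hit_count_matches_degeneracy_oracle(self):
        # expected hits = (L - w + 1) * prod(|choices| / 4)
        pattern = "RCGTW"
        per_site = (2 / 4) * (1 / 4) ** 3 * (2 / 4)
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(40):
            prom = "".join(rng.choice(list("ACGT"), 1_500))
            hits = scan_elements("g", prom,
                                 [CatalogEntry("X", pattern, "t")],
                                 both_strands=False)
            counts.append(len(hits))
        n_sites = 1_500 - len(pattern) + 1
        expected = n_sites * per_site
        sd = np.sqrt(n_sites * per_site * (1 - per_site) / 40)
        assert abs(np.mean(counts) - expected) < 3 * sd

    def test_packaged_catalog_valid(self):
        validate_catalog(default_catalog())


def oracle_upper_tail(k, n, p):
    return sum(comb(n, i) * p ** i * (1 - p) ** (n - i)
               for i in range(k, n + 1))


class TestExactBinomial:
    def test_zero_successes_tail_is_one(self):
        assert exact_binom_upper(0, 10, 0.3) == 1.0

    def test_hand_value_eight_of_ten(self):
        # P(X >= 8), X ~ Bin(10, 0.5) = (45 + 10 + 1) / 1024
        assert exact_binom_upper(8, 10, 0.5) == pytest.approx(56 / 1024,
                                                              abs=1e-12)

    def test_hand_value_ten_of_ten(self):
        assert exact_binom_upper(10, 10, 0.5) == pytest.approx(2 ** -10,
                                                               abs=1e-15)

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_summed_pmf_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(1, 61))
        k = int(rng.integers(0, n + 1))
        p = float(rng.uniform(0.01, 0.99))
        assert exact_binom_upper(k, n, p) == pytest.approx(
            oracle_upper_tail(k, n, p), abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        vals = [exact_binom_upper(k, 25, 0.4) for k in range(26)]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))


class TestEnrichment:
    def _hits(self, carriers, element="ABRE"):
        return {g: ([ElementHit(g, element, 0, "+", "ACGTGGC")]
                    if g in carriers else []) for g in self.genes}

    genes = [f"g{i}" for i in range(12)]

    def test_planted_subfamily_attains_smallest_q(self):
        # subfamily A carries the element in 5/6; B in 1/6
        sfmap = {g: ("A" if i < 6 else "B") for i, g in enumerate(self.genes)}
        carriers = set(self.genes[:5]) | {self.genes[6]}
        results = enrichment_test(self._hits(carriers), sfmap)
        by_sf = {(r.subfamily): r for r in results if r.element == "ABRE"}
        assert by_sf["A"].p_value < by_sf["B"].p_value
        assert by_sf["A"].k == 5 and by_sf["A"].n == 6
        assert by_sf["A"].p0 == pytest.approx(6 / 12)

    def test_q_at_least_p(self):
        sfmap = {g: ("A" if i % 2 else "B") for i, g in enumerate(self.genes)}
        results = enrichment_test(self._hits(set(self.genes[:4])), sfmap)
        for r in results:
            assert r.q_value >= r.p_value - 1e-15

    def test_empty_subfamily_omitted(self):
        sfmap = {g: "A" for g in self.genes}
        results = enrichment_test(self._hits(set()), sfmap,
                                  elements=["ABRE"])
        assert {r.subfamily for r in results} == {"A"}
        assert all(r.p_value == 1.0 for r in results)

    def test_planted_scenario_recovery(self, small_genome, small_scenario):
        """Planted subfamily-specific elements rank top in their subfamily."""
        from hdzipkit.genestruct import read_gene_models
        genome, gff, truth = small_genome
        models = read_gene_models(gff)
        catalog = default_catalog()
        hits = {}
        for gid, model in models.items():
            prom, _ = extract_promoter(genome, model)
            hits[gid] = scan_elements(gid, prom, catalog)
        results = enrichment_test(hits, truth.true_subfamily,
                                  [e.name for e in catalog])
        # the generator plants ABRE at elevated frequency in subfamily I
        sub = [r for r in results if r.subfamily == "I"]
        abre = next(r for r in sub if r.element == "ABRE")
        assert abre.k >= abre.n - 1  # nearly every promoter carries it
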