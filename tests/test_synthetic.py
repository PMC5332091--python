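"""Generator contracts: determinism, planted truth, calibration."""

import numpy as np
import pytest

from hdzipkit import synthetic
from hdzipkit.domains import subfamily_consensus
from hdzipkit.synthetic import (DuplicationSpec, ExpressionPlan, QpcrPlan,
                                ScenarioConfig, TruthTable, generate_expression,
                                generate_genome, generate_proteome)


def _empty_config(**kw):
    base = dict(
        seed=1, n_chromosomes=2, chromosome_length=300_000,
        archetype_counts={"I": 0, "II": 0, "III": 0, "IV": 0},
        decoy_counts={}, duplication_plan=[], scaffold_genes=0,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestProteomeGeneration:
    def test_empty_plan_empty_outputs(self):
        records, truth = generate_proteome(_empty_config())
        assert records == []
        assert truth.true_family_ids == []

    def test_noiseless_member_contains_exact_consensus(self):
        cfg = _empty_config(archetype_counts={"I": 1, "II": 0, "III": 0,
                                              "IV": 0},
                            domain_mutation_rate=0.0)
        records, truth = generate_proteome(cfg)
        ((gid, seq),) = records
        assert subfamily_consensus("I", "HD") in seq
        assert subfamily_consensus("I", "LZ") in seq

    def test_seeded_runs_byte_identical(self, small_scenario, tmp_path):
        p1, p2 = tmp_path / "a.faa", tmp_path / "b.faa"
        generate_proteome(small_scenario, p1)
        generate_proteome(small_scenario, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truth_ids_exist_in_records(self, small_proteome):
        records, truth = small_proteome
        ids = {r for r, _ in records}
        assert set(truth.true_family_ids) <= ids
        for group in truth.decoy_ids.values():
            assert set(group) <= ids

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            generate_proteome(_empty_config(
                archetype_counts={"I": -1, "II": 0, "III": 0, "IV": 0}))

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(_empty_config(chromosome_length=0))


class TestGenomeGeneration:
    def test_perfect_identity_copy_verbatim(self, noiseless_scenario):
        genome, gff, truth = generate_genome(noiseless_scenario)
        (dup,) = truth.true_duplications
        a, b = truth.gene_loci[dup["gene_a"]], truth.gene_loci[dup["gene_b"]]
        wa = genome[a["chromosome"]][a["start"] - 50_000:a["end"] + 50_000]
        wb = genome[b["chromosome"]][b["start"] - 50_000:b["end"] + 50_000]
        assert wa == wb

    def test_layout_plants_no_tandem_pairs(self, small_genome):
        genome, gff, truth = small_genome
        loci = sorted(
            ((v["chromosome"], v["start"], v["end"]) for v in
             truth.gene_loci.values()))
        for (c1, s1, e1), (c2, s2, e2) in zip(loci, loci[1:]):
            if c1 == c2:
                assert s2 - e1 > 50_000

    def test_flank_divergence_matches_binomial(self, small_genome):
        genome, gff, truth = small_genome
        for dup in truth.true_duplications:
            a = truth.gene_loci[dup["gene_a"]]
            b = truth.gene_loci[dup["gene_b"]]
            wa = np.frombuffer(genome[a["chromosome"]]
                               [a["start"] - 50_000:a["end"] + 50_000]
                               .encode(), dtype=np.uint8)
            wb = np.frombuffer(genome[b["chromosome"]]
                               [b["start"] - 50_000:b["end"] + 50_000]
                               .encode(), dtype=np.uint8)
            n = len(wa)
            rate = 1 - dup["flank_identity"]
            mism = int((wa != wb).sum())
            sd = np.sqrt(n * rate * (1 - rate))
            assert abs(mism - n * rate) < 3 * sd

    def test_determinism(self, small_scenario):
        g1, gff1, _ = generate_genome(small_scenario)
        g2, gff2, _ = generate_genome(small_scenario)
        assert g1 == g2 and gff1 == gff2

    def test_invalid_flank_identity_rejected(self):
        cfg = _empty_config(
            archetype_counts={"I": 2, "II": 0, "III": 0, "IV": 0},
            duplication_plan=[DuplicationSpec("I", flank_identity=0.0)])
        with pytest.raises(ValueError):
            generate_genome(cfg)

    def test_overfull_chromosome_names_genes(self):
        cfg = _empty_config(
            n_chromosomes=1, chromosome_length=150_000,
            archetype_counts={"I": 3, "II": 0, "III": 0, "IV": 0})
        with pytest.raises(ValueError, match="do not fit"):
            generate_genome(cfg)


class TestExpressionGeneration:
    def test_constitutive_always_above_threshold(self, noiseless_scenario):
        fpkm, ct, truth = generate_expression(noiseless_scenario)
        samples = noiseless_scenario.expression_plan.samples
        for g, cls in truth.true_expression_class.items():
            values = fpkm.loc[g, samples]
            if cls == "constitutive":
                assert (values > 1.0).all()
            elif cls == "non_expressed":
                assert (values <= 1.0).all()

    def test_null_qpcr_effect_gives_unit_ratio(self):
        from hdzipkit.expression import analyze_qpcr
        cfg = _empty_config(
            archetype_counts={"I": 2, "II": 0, "III": 0, "IV": 0},
            qpcr_plan=QpcrPlan(n_genes=1, ct_sd=0.0,
                               timepoints=["NTC", "t1"]))
        fpkm, ct, truth = generate_expression(cfg)
        # overwrite truth effect: regenerate with ratio forced to 1 by
        # patching the table — target Ct constant across samples
        g = list(truth.true_qpcr_ratio)[0]
        base = ct[(ct.target == g) & (ct["sample"] == "NTC")].ct.iloc[0]
        ct.loc[ct.target == g, "ct"] = base
        res = analyze_qpcr(ct, "NTC")
        assert all(r.relative_expression == pytest.approx(1.0) for r in res)

    def test_fourfold_effect_is_two_cycles(self):
        cfg = _empty_config(
            archetype_counts={"I": 1, "II": 0, "III": 0, "IV": 0},
            qpcr_plan=QpcrPlan(n_genes=1, ct_sd=0.0,
                               timepoints=["NTC", "t1"]))
        fpkm, ct, truth = generate_expression(cfg)
        g = list(truth.true_qpcr_ratio)[0]
        ratio = truth.true_qpcr_ratio[g]["t1"]
        ct_ntc = ct[(ct.target == g) & (ct["sample"] == "NTC")].ct.iloc[0]
        ct_t1 = ct[(ct.target == g) & (ct["sample"] == "t1")].ct.iloc[0]
        assert ct_ntc - ct_t1 == pytest.approx(np.log2(ratio), abs=1e-3)

    def test_negative_ct_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_expression(_empty_config(
                qpcr_plan=QpcrPlan(ct_sd=-0.1)))

    def test_empty_sample_plan_rejected(self):
        with pytest.raises(ValueError):
            generate_expression(_empty_config(
                expression_plan=ExpressionPlan(samples=[])))


class TestTruthTable:
    def test_round_trip_json(self, small_proteome, tmp_path):
        _, truth = small_proteome
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthTable.from_json(path)
        assert back.true_family_ids == truth.true_family_ids
        assert back.true_subfamily == truth.true_subfamily

    def test_duplication_pairs_unordered_unique(self, small_genome):
        _, _, truth = small_genome
        pairs = truth.duplication_pairs()
        assert len(pairs) == len(truth.true_duplications)
        for p in pairs:
            assert len(p) == 2
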