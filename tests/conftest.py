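import numpy as np
import pytest

from hdzipkit import synthetic


@pytest.fixture(scope="session")
def small_scenario():
    """Compact scenario: 4/3/2/2 members, a few decoys, two duplications."""
    return synthetic.ScenarioConfig(
        seed=11,
        n_chromosomes=6,
        chromosome_length=400_000,
        archetype_counts={"I": 4, "II": 3, "III": 2, "IV": 2},
        decoy_counts={"single_hd": 4, "single_lz": 4, "random": 2,
                      "duplicate": 2},
        duplication_plan=[
            synthetic.DuplicationSpec("I", 0.92),
            synthetic.DuplicationSpec("II", 0.90),
        ],
        scaffold_genes=1,
        exon_counts={"I": 2, "II": 3, "III": 18, "IV": 10},
        expression_plan=synthetic.ExpressionPlan(
            class_counts={"constitutive": 4, "non_expressed": 2,
                          "tissue_specific": 3, "partial": 2},
            drought_changed={"leaf": 3, "root": 4}),
        qpcr_plan=synthetic.QpcrPlan(n_genes=3),
    )


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Mutation-free, noise-free scenario for exact truth recovery."""
    return synthetic.ScenarioConfig(
        seed=7,
        n_chromosomes=4,
        chromosome_length=400_000,
        archetype_counts={"I": 3, "II": 3, "III": 2, "IV": 2},
        decoy_counts={"single_hd": 3, "single_lz": 3, "random": 2,
                      "duplicate": 2},
        duplication_plan=[synthetic.DuplicationSpec("I", 1.0)],
        scaffold_genes=0,
        domain_mutation_rate=0.0,
        expression_plan=synthetic.ExpressionPlan(
            class_counts={"constitutive": 3, "non_expressed": 2,
                          "tissue_specific": 3, "partial": 2},
            drought_changed={"leaf": 3, "root": 2}),
        qpcr_plan=synthetic.QpcrPlan(n_genes=3, ct_sd=0.0),
    )


@pytest.fixture(scope="session")
def small_proteome(small_scenario):
    return synthetic.generate_proteome(small_scenario)


@pytest.fixture(scope="session")
def small_genome(small_scenario):
    return synthetic.generate_genome(small_scenario)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
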