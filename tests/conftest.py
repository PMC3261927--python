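import numpy as np
import pytest

from tissueqtl.simulate import (
    SimulationConfig,
    plan_effects,
    simulate_all_genotypes,
    simulate_expression,
)


@pytest.fixture(scope="session")
def two_cohort_data():
    """Small two-cohort dataset with planted effects of all architectures."""
    config = SimulationConfig(
        n_samples_per_cohort={"reference": 300, "target": 74},
        n_snps=400,
        n_probes=40,
        ld_block_size=5,
        flip_prob=0.03,
        n_global_factors=0,
        shared_individuals=False,
        seed=42,
    )
    genotypes = simulate_all_genotypes(config)
    effects, truth = plan_effects(
        config,
        {
            "concordant": 5,
            "specific": 5,
            "alternative": 5,
            "different_effect_size": 5,
            "opposite_direction": 5,
        },
        reference="reference",
        target="target",
        ve_target=0.35,
        ve_reference=0.05,
        weak_ve=0.02,
    )
    expr = simulate_expression(genotypes, effects, config)
    return config, genotypes, expr, effects, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
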