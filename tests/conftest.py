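import dataclasses

import pytest

from sirvpop.pipeline import run_demo
from sirvpop.simulate import SimulationConfig, simulate_population

# Reduced-scale study conditions used throughout the suite: small enough for
# fast end-to-end runs, large enough that every structural signal (regional
# clades, core/variable split, local spacer bias) is present.
SMALL = SimulationConfig(
    seed=1,
    viruses_per_region=3,
    hosts_per_region=2,
    spacers_per_host=12,
    genome_length=12000,
    genome_length_sd=400,
    n_core_genes=8,
    n_variable_pool=16,
    host_genome_length=5000,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def demo_result(small_config):
    """Full pipeline run against the small synthetic population."""
    return run_demo(seed=small_config.seed, sim_config=small_config)


@pytest.fixture()
def no_evolution_config(small_config):
    return dataclasses.replace(
        small_config,
        core_substitution_rate=0.0,
        variable_substitution_rate=0.0,
        gene_gain_loss_rate=0.0,
        genome_length_sd=0,
        spacer_divergence_local=0.0,
    )
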