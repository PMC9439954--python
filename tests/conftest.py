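import numpy as np
import pytest

from amphikit import simdata


@pytest.fixture(scope="session")
def triploid_config():
    """A small amphitriploid genome: 5 chromosomes x 300 kb, d1 = 33."""
    return simdata.SimConfig(
        n_chromosomes=5, chrom_length=300_000, ploidy=3,
        pairwise_divergence=0.005, depth_per_haplotype=33.0, seed=11)


@pytest.fixture(scope="session")
def triploid_genome(triploid_config):
    genome, truth = simdata.simulate_founder(triploid_config)
    return genome


@pytest.fixture(scope="session")
def triploid_records(triploid_config, triploid_genome):
    return simdata.simulate_depths(triploid_genome, triploid_config)


@pytest.fixture(scope="session")
def diploid_config():
    return simdata.SimConfig(
        n_chromosomes=5, chrom_length=300_000, ploidy=2,
        pairwise_divergence=0.005, depth_per_haplotype=33.0, seed=12)


@pytest.fixture(scope="session")
def diploid_records(diploid_config):
    genome, _ = simdata.simulate_founder(diploid_config)
    return simdata.simulate_depths(genome, diploid_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
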