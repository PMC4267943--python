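import pytest

from nqospec import SimConfig, simulate_genome, simulate_mutagenesis


@pytest.fixture(scope="session")
def small_cohort():
    """A 2 Mbp, 8-strain cohort with 2 hypermutators, fixed seed."""
    config = SimConfig(
        seed=7, total_length=2_000_000, n_strains=8, n_hypermutators=2
    )
    genome, annot = simulate_genome(config)
    per_strain, truth, table = simulate_mutagenesis(genome, config)
    return config, genome, annot, per_strain, truth, table


@pytest.fixture(scope="session")
def small_genome(small_cohort):
    return small_cohort[1]
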