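import pytest

from roimeth.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def small_config():
    """Fast, small-but-complete study design for unit/pipeline tests."""
    return SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=4_000,
        n_regions=4,
        region_length=800,
        coverage_prob=0.5,
        depth_mean=5.0,
        cohort_sizes={"MC": 2, "HC": 2, "GBM1": 3, "GBM2": 3},
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A written-out small synthetic dataset, shared across tests."""
    out = tmp_path_factory.mktemp("dataset")
    config = SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=4_000,
        n_regions=4,
        region_length=800,
        coverage_prob=0.5,
        depth_mean=5.0,
        cohort_sizes={"MC": 2, "HC": 2, "GBM1": 3, "GBM2": 3},
    )
    paths = simulate_dataset(config, out)
    return config, paths
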