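import pytest

from wadermhc.simulate import SimulationConfig, generate_allele_pool, simulate


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A down-scaled but otherwise default-structured experiment."""
    return SimulationConfig(
        n_individuals=10,
        n_duplicate_pairs=3,
        depth_mean=6000.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate(small_cfg)


@pytest.fixture(scope="session")
def default_pool():
    cfg = SimulationConfig(seed=5)
    return generate_allele_pool(cfg)


def zero_noise_cfg(seed: int, n_individuals: int = 8) -> SimulationConfig:
    return SimulationConfig(
        n_individuals=n_individuals,
        n_duplicate_pairs=2,
        depth_mean=6000.0,
        pcr_error_rate=0.0,
        chimera_rate=0.0,
        amplification_bias_sd=0.0,
        seed=seed,
    )
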