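import numpy as np
import pytest

from dasypop import LandscapeConfig, RunConfig, generate_truth, run_experiment


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """Desk-scale landscape small enough for per-test pipeline runs."""
    return LandscapeConfig(
        seed=7,
        grid_shape=(48, 48),
        n_coarse_units=12,
        fine_per_coarse=4,
        pop_total=200_000,
    )


@pytest.fixture(scope="session")
def truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    """One full paired-experiment run, shared across read-only tests."""
    return run_experiment(RunConfig(landscape=small_config, n_trees=150))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231012)
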