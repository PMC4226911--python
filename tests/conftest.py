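import numpy as np
import pytest

from mirscreen.simulate import SimulationConfig, simulate_screen
from mirscreen.quantify import normalize_screen


def noise_free_config(**overrides) -> SimulationConfig:
    base = dict(
        n_mirnas=6, n_transfections=2, n_blots_per_transfection=1,
        membrane_sd=0.0, efficiency_sd=0.0, noise_sd=0.0, dropout_prob=0.0,
        rng_seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def small_noisy_config(**overrides) -> SimulationConfig:
    base = dict(n_mirnas=8, mirnas_per_membrane=8, rng_seed=0)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def noise_free_screen():
    config = noise_free_config()
    table, truth = simulate_screen(config)
    return config, table, truth


@pytest.fixture
def noisy_corrected():
    config = small_noisy_config(rng_seed=11)
    table, truth = simulate_screen(config)
    return normalize_screen(table), truth


def random_guide(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def random_target(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
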