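import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from mirlearn.quantify import HairpinRecord
from mirlearn.simulate import SimulationConfig, generate_hairpin_set
from mirlearn.thermo import EnergyModel


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    return EnergyModel.default()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        rng_seed=42,
        n_mirnas=20,
        library_depths={"naive": 5000, "1h": 5000},
        planted_effects={},
    )


@pytest.fixture(scope="session")
def hairpins(small_config) -> list[HairpinRecord]:
    return generate_hairpin_set(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240301)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
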