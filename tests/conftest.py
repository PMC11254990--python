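import numpy as np
import pytest

from odoxpk import (PopulationModel, Regimen, StructuralParams,
                    default_population_model, default_structural_params)


@pytest.fixture(scope="session")
def theta() -> StructuralParams:
    return default_structural_params()


@pytest.fixture(scope="session")
def pop() -> PopulationModel:
    return default_population_model()


@pytest.fixture(scope="session")
def noiseless_pop(theta) -> PopulationModel:
    return PopulationModel(theta=theta)


@pytest.fixture(scope="session")
def iv_regimen() -> Regimen:
    return Regimen.single_iv(130.0, duration=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_params(rng: np.random.Generator) -> StructuralParams:
    """A physiologically shaped random parameter set for solver sweeps."""
    return StructuralParams(
        cl_u=rng.uniform(2000, 15000),
        v1_u=rng.uniform(1000, 8000),
        v2_u=rng.uniform(2000, 10000),
        v3_u=rng.uniform(20000, 90000),
        q2_u=rng.uniform(1000, 8000),
        q3_u=rng.uniform(500, 4000),
        ka=rng.uniform(0.2, 2.5),
        tlag=rng.uniform(0.0, 1.0),
        f_oral=rng.uniform(0.05, 0.6),
        fu_iv=0.0067,
        fu_po=0.0102,
    )
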