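import numpy as np
import pytest

from prpflux.kinetics import CellPopulation, KineticParams, ProbeModel
from prpflux.simulate import scenario


@pytest.fixture(scope="session")
def stress_params() -> KineticParams:
    params, _, _ = scenario("prpstar_stress")
    return params


@pytest.fixture(scope="session")
def basal_params() -> KineticParams:
    params, _, _ = scenario("prpstar_basal")
    return params


@pytest.fixture(scope="session")
def saturating_probe() -> ProbeModel:
    return ProbeModel(concentration=200.0)


@pytest.fixture
def small_pop() -> CellPopulation:
    return CellPopulation(n_cells=2000)


def random_params(rng: np.random.Generator) -> KineticParams:
    """Random rate set with a random (normalized) initial occupancy."""
    rates = rng.uniform(0.005, 0.3, size=4)
    f0 = rng.dirichlet(np.ones(4))
    return KineticParams(k_exit=rates[0], k_gp=rates[1], k_endo=rates[2],
                         k_deg=rates[3], f0=tuple(f0))
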