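import numpy as np
import pytest
from hypothesis import settings

from vasoperf import (BoundaryConditions, CapillaryParameters, CoupledProblem,
                      FlowParameters, ModelVariant, fixture_mini_organ,
                      fixture_minimal_loop, mmhg_to_kpa, solve)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def flow_params():
    return FlowParameters()


@pytest.fixture(scope="session")
def capillary_params():
    return CapillaryParameters()


@pytest.fixture(scope="session")
def bc():
    return BoundaryConditions(mmhg_to_kpa(30.0), mmhg_to_kpa(7.5))


@pytest.fixture(scope="session")
def minimal_loop():
    return fixture_minimal_loop()


@pytest.fixture(scope="session")
def mini_organ():
    art, ven, grid, spec = fixture_mini_organ()
    return art, ven, grid


@pytest.fixture(scope="session")
def solved_mini_organ(mini_organ, flow_params, capillary_params, bc):
    """Converged solutions per variant on the shared mini-organ geometry."""
    art, ven, grid = mini_organ
    cache = {}

    def get(name: str):
        if name not in cache:
            problem = CoupledProblem(art, ven, grid, flow_params, capillary_params, bc,
                                     variant=ModelVariant.from_name(name))
            cache[name] = solve(problem)
        return cache[name]

    return get
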