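import numpy as np
import pytest

from aomrtm import fixtures
from aomrtm.grid_and_state import SpeciesRegistry, State, build_grid


@pytest.fixture(scope="session")
def registry():
    return SpeciesRegistry()


@pytest.fixture()
def grid():
    return build_grid(depth_max=80.0, n_cells=100)


@pytest.fixture()
def flat_grid():
    """Constant-porosity grid (phi = 0.9) for closed-form comparisons."""
    return build_grid(depth_max=40.0, n_cells=80,
                      porosity_surface=0.9, porosity_deep=0.9)


@pytest.fixture()
def rng():
    return np.random.default_rng(20190614)


@pytest.fixture(scope="session")
def toy():
    """(ModelParams, Scenario) of the fast miniature column."""
    return fixtures.toy_column()


@pytest.fixture(scope="session")
def toy_run(toy):
    """One completed toy run shared across tests (read-only)."""
    from aomrtm.simulator import Simulator

    params, scenario = toy
    sim = Simulator(params, scenario)
    traj = sim.run()
    return sim, traj


def random_state(grid, registry, rng, scale=1e-6) -> State:
    state = State.zeros(grid, registry)
    state.solutes = rng.uniform(0.0, scale, state.solutes.shape)
    state.solids = rng.uniform(0.0, 1e-4, state.solids.shape)
    state.microbes = rng.uniform(0.0, 1e8, state.microbes.shape)
    return state
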