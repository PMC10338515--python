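import numpy as np
import pytest

from phrenosweep import PigParams, VentilatorSettings
from phrenosweep.evaluation import PatternGrid, enumerate_grid, run_sweep


@pytest.fixture(scope="session")
def default_pig() -> PigParams:
    return PigParams()

@pytest.fixture(scope="session")
def quiet_pig(default_pig) -> PigParams:
    return default_pig.noiseless()

@pytest.fixture(scope="session")
def vent() -> VentilatorSettings:
    return VentilatorSettings()

@pytest.fixture(scope="session")
def canonical_grid():
    return enumerate_grid()

@pytest.fixture(scope="session")
def baseline_only_grid(canonical_grid):
    """Grid with no patterns: executing it yields one baseline record."""
    return PatternGrid(patterns=(), baseline=canonical_grid.baseline,
                       config=canonical_grid.config)

@pytest.fixture(scope="session")
def full_sweep(canonical_grid, default_pig, vent):
    """One full 281-pattern sweep on the default animal, shared across
    acceptance tests (seed fixed once for the suite)."""
    return run_sweep(canonical_grid, default_pig, vent, seed=1)

@pytest.fixture(scope="session")
def full_sweep_frame(full_sweep):
    return full_sweep.to_frame()

@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
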