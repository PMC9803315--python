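import numpy as np
import pytest

from fibrocontrol import (
    SimulationSettings,
    assemble_fibroblast_system,
    assemble_myofibroblast_system,
    build_grid,
    default_parameters,
)


@pytest.fixture(scope="session")
def params():
    """Default tabulated parameter triple (myofibroblast, fibroblast, homog)."""
    return default_parameters()


@pytest.fixture(scope="session")
def grid36():
    """The published working grid: 36 interior nodes (n = 7)."""
    return build_grid(6)


@pytest.fixture(scope="session")
def grid1():
    """Single well-mixed interior node."""
    return build_grid(1)


@pytest.fixture(scope="session")
def system36(params, grid36):
    myof, _, homog = params
    return assemble_myofibroblast_system(myof, homog, grid36)


@pytest.fixture(scope="session")
def one_node_systems(params, grid1):
    myof, fib, homog = params
    return (
        assemble_myofibroblast_system(myof, homog, grid1),
        assemble_fibroblast_system(fib, myof, homog, grid1),
    )


@pytest.fixture
def settings():
    return SimulationSettings()


def scalar_care(a: float, b: float) -> float:
    """Closed-form 1-node Riccati solution (a + sqrt(a^2 + b^2)) / b^2."""
    return (a + np.hypot(a, b)) / b**2
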