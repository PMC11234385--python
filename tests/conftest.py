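"""Shared fixtures: reference models, cycles and trajectories.

Expensive objects (limit cycles, reference trajectories) are session-scoped
so the suite integrates each reference system only once.
"""

import numpy as np
import pytest

from orbitempo.dynamics import find_limit_cycle, integrate
from orbitempo.models import (
    build_bistable_switch,
    build_neural_tube,
    build_repressilator_reduced,
    default_initial_state,
    default_neural_tube_params,
)


@pytest.fixture(scope="session")
def reduced_model():
    return build_repressilator_reduced()


@pytest.fixture(scope="session")
def reduced_x0(reduced_model):
    return default_initial_state(reduced_model)


@pytest.fixture(scope="session")
def reduced_cycle(reduced_model, reduced_x0):
    """Reference limit cycle of the reduced repressilator: (orbit, period)."""
    return find_limit_cycle(reduced_model, reduced_x0, n_points=500)


@pytest.fixture(scope="session")
def neural_model():
    return build_neural_tube(default_neural_tube_params(), shh_level=1.0)


@pytest.fixture(scope="session")
def neural_x0(neural_model):
    return default_initial_state(neural_model)


@pytest.fixture(scope="session")
def neural_reference(neural_model, neural_x0):
    """Reference V3 differentiation trajectory under high Shh."""
    return integrate(neural_model, neural_x0, (0.0, 80.0))


@pytest.fixture(scope="session")
def bistable_model():
    return build_bistable_switch()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
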