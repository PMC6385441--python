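import functools

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from yeastiron.mb_data import load_fixture_tables
from yeastiron.ode_models import build_system
from yeastiron.params import CompartmentGeometry, Condition, canonical_parameters
from yeastiron.steady_state import solve_steady


@pytest.fixture(scope="session")
def geometry():
    return CompartmentGeometry()


@pytest.fixture(scope="session")
def wt():
    return canonical_parameters("WT")


@pytest.fixture(scope="session")
def dd():
    return canonical_parameters("DD")


@pytest.fixture(scope="session")
def records(geometry):
    return load_fixture_tables(geometry)


@pytest.fixture(scope="session")
def c9_steady(wt, dd, geometry):
    """Memoized C9 steady-state solver keyed by (strain, N)."""
    params = {"WT": wt, "DD": dd}

    @functools.cache
    def solve(strain: str, N: float):
        system = build_system("C9", Condition(strain, N), params[strain], geometry)
        return solve_steady(system)

    return solve
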