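import warnings

import pytest

from lobulesim.fixtures import generate_fixture
from lobulesim.flow import solve_steady_flow
from lobulesim.lattice import build_unit_cell
from lobulesim.properties import FlowProperties


@pytest.fixture(scope="session")
def base_props():
    return FlowProperties()


@pytest.fixture(scope="session")
def unit_cell(base_props):
    return build_unit_cell(base_props)


@pytest.fixture(scope="session")
def chain10():
    """1x1x10 duct lattice with its steady flow solution."""
    lat, _ = generate_fixture("chain", n=10)
    return lat, solve_steady_flow(lat, delta_p=100.0)


@pytest.fixture(scope="session")
def tiny6():
    lat, _ = generate_fixture("tiny_lobule", n=6)
    return lat


@pytest.fixture(scope="session")
def tiny6_flow(tiny6):
    return solve_steady_flow(tiny6, delta_p=100.0)


@pytest.fixture(autouse=True)
def _no_spanning_warnings():
    """Silence the expected no-spanning-cluster warnings in percolation sweeps."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no inlet-outlet spanning")
        yield
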