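import pytest
from hypothesis import HealthCheck, settings

from dtrips import CableParameters, make_binary_tree, make_cable, make_double_junction_tree, make_y_tree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Standard physical membrane parameters (uF cm^-2, Ohm cm^2, Ohm cm)."""
    return CableParameters(C=1.0, R=3000.0, Ra=100.0)


@pytest.fixture(scope="session")
def y_tree(params):
    """Three equal branches around a degree-3 node B; terminals A, C, D."""
    return make_y_tree(100.0, 1.0, params)


@pytest.fixture(scope="session")
def double_junction_tree(params):
    """Five-branch structure with junctions B and C."""
    return make_double_junction_tree(80.0, 1.0, params)


@pytest.fixture(scope="session")
def cable(params):
    """A sealed 500 um cable."""
    return make_cable(500.0, 1.0, params)


@pytest.fixture(scope="session")
def tree_a3():
    """Depth-3 binary tree with the dimensionless parameter set."""
    p = CableParameters.from_diffusion(D=1.0, tau=1.0, a=0.05, C=1.0, dimensionless=True)
    return make_binary_tree(3, 0.3, 0.05, p)
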