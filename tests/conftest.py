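import pytest
from hypothesis import settings

import ovarlap as ov

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def painful_world():
    return ov.two_goal_corridor()


@pytest.fixture(scope="session")
def painless_world():
    return ov.four_goal_arena()


@pytest.fixture(scope="session")
def basis_theta1():
    """A noiseless basis at moderate generalization, shared across tests."""
    return ov.build_basis(ov.BasisSpec(theta=1.0, seed=12345))
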