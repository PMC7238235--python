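import pytest
from hypothesis import HealthCheck, settings

import tabscale as ts

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def xl100():
    return ts.load_fixture("XL100")


@pytest.fixture(scope="session")
def xl400():
    return ts.load_fixture("XL400")


@pytest.fixture(scope="session")
def stylone():
    return ts.load_fixture("StylOne")


def operating_point(np_=20.0, nt=20.0, stress=150.0, tablet_mg=725.0, mass_flow=None):
    return ts.OperatingPoint(
        turret_frequency=nt,
        paddle_frequency=np_,
        target_stress=stress,
        tablet_weight=tablet_mg * 1e-6,
        mass_flow=mass_flow,
    )


@pytest.fixture
def op_factory():
    return operating_point
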