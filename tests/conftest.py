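import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dloplan import (  # noqa: E402
    PlanParameters,
    fixture_f1,
    fixture_f2,
    generate_cohort,
)


@pytest.fixture(scope="session")
def f1():
    """Moderate varus reference limb (MPTA 81.5, LDFA 93.1, JLCA 0)."""
    return fixture_f1()


@pytest.fixture(scope="session")
def f2():
    """Severe varus limb (MPTA 80, LDFA 94, JLCA 4)."""
    return fixture_f2()


@pytest.fixture(scope="session")
def cohort():
    """Seeded 23-limb synthetic varus cohort."""
    return generate_cohort(n=23, seed=42)


@pytest.fixture(scope="session")
def bone_params():
    """Planning parameters for bone-only comparisons against the rigid
    simulator (no soft-tissue deduction, which the simulator cannot see)."""
    return PlanParameters(apply_jlca_adjustment=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
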