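import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from seafloor_energy import (
    BurrowerPopulation,
    FluidConstants,
    default_aragonite_kinetics,
    synthesize_reworking_table,
)


@pytest.fixture(scope="session")
def kin():
    return default_aragonite_kinetics()


@pytest.fixture(scope="session")
def fluid():
    return FluidConstants()


@pytest.fixture(scope="session")
def default_pops():
    """Default synthetic reworking table (fixed seed)."""
    return synthesize_reworking_table(seed=7)


@pytest.fixture
def burrower():
    return BurrowerPopulation(
        taxon="test", group="testgroup", R=0.1, b=0.005, d=0.05, mode="both", G_c=1.0
    )
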