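import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from ahmt import profiles
from ahmt.scheduler import plan_series

# Published transfer table for the six diluted levels:
# target -> ((t_WS, p_WS), (t_DBGE, p_DBGE)), times in min, pressures in psi.
EXPECTED_PCR = {
    6.25: ((10, 2.5), (15, 25.0)),
    12.5: ((10, 5.0), (14, 25.0)),
    25.0: ((10, 10.0), (10, 30.0)),
    37.5: ((10, 15.0), (10, 25.0)),
    50.0: ((10, 20.0), (10, 20.0)),
    75.0: ((10, 30.0), (10, 10.0)),
}
EXPECTED_NANO = {
    6.25: ((5, 0.5), (10, 3.8)),
    12.5: ((10, 0.5), (10, 3.5)),
    25.0: ((10, 1.0), (10, 3.0)),
    37.5: ((10, 1.5), (10, 2.5)),
    50.0: ((10, 2.0), (10, 2.0)),
    75.0: ((10, 3.0), (10, 1.0)),
}


@pytest.fixture(scope="session")
def pcr_schedules():
    return plan_series(
        list(EXPECTED_PCR), profiles.STOCK_CONCENTRATION,
        profiles.PCR_BUDGET, profiles.PCR_CONSTRAINTS,
    )


@pytest.fixture(scope="session")
def nano_schedules():
    return plan_series(
        list(EXPECTED_NANO), profiles.STOCK_CONCENTRATION,
        profiles.NANOVIAL_BUDGET, profiles.NANOVIAL_CONSTRAINTS,
    )


@pytest.fixture(scope="session")
def geometry():
    return profiles.REFERENCE_GEOMETRY


@pytest.fixture(scope="session")
def fluid():
    return profiles.WATER
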