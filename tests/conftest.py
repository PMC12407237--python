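import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from axspa_burden import (
    SyntheticScenario,
    generate_life_table,
    generate_parameter_set,
    run_cohort,
)
from axspa_burden.mortality import LifeTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params():
    """Default synthetic study conditions (fixed seed)."""
    return generate_parameter_set(SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table(1)


@pytest.fixture(scope="session")
def no_mortality_table():
    """A life table with no deaths until the closing age, isolating the
    diagnosis process."""
    qx = {s: np.zeros(101) for s in ("male", "female")}
    for s in qx:
        qx[s][-1] = 1.0
    return LifeTable(min_age=0, max_age=100, qx=qx).validate()


@pytest.fixture(scope="session")
def trace_male(params, life_table):
    return run_cohort(params, life_table, "male")


@pytest.fixture(scope="session")
def trace_female(params, life_table):
    return run_cohort(params, life_table, "female")
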