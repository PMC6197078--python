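import pytest
from hypothesis import HealthCheck, settings

import radfrac as rf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """The seven-patient fixture cohort."""
    return rf.load_cohort("table1")


@pytest.fixture(scope="session")
def by_id(cohort):
    return {p.id: p for p in cohort}


@pytest.fixture(scope="session")
def patient_a(by_id):
    return by_id["A"]


@pytest.fixture(scope="session")
def patient_b(by_id):
    return by_id["B"]
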