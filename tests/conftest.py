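import pytest
from hypothesis import HealthCheck, settings

from infant_ee.processing import process_trace
from infant_ee.records import InfantRecord
from infant_ee.synthetic import CohortParams, generate_cohort, simulate_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: weight implied by the reference mean anthropometrics (BMI 15.5, length 68.8)
REFERENCE_WEIGHT = 15.5 * 0.688**2


@pytest.fixture(scope="session")
def mean_male():
    return InfantRecord(id="m", sex="male", age_months=5.0, length_cm=68.8, bmi=15.5)


@pytest.fixture(scope="session")
def mean_female():
    return InfantRecord(id="f", sex="female", age_months=5.0, length_cm=68.8, bmi=15.5)


@pytest.fixture(scope="session")
def clone_cohort():
    """Ten clones of the reference mean infant, 7 male / 3 female."""
    return generate_cohort(
        CohortParams(age_sd=0.0, length_sd=0.0, bmi_sd=0.0), seed=0
    )


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(seed=42)


@pytest.fixture(scope="session")
def default_profiles(default_study):
    return [process_trace(s.trace, s.infant) for s in default_study]
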