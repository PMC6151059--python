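import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from msas.scoring import builtin_rubric  # noqa: E402
from msas.synthetic import default_config, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def msas_rubric():
    return builtin_rubric("msas")


@pytest.fixture(scope="session")
def sas_rubric():
    return builtin_rubric("sas")


@pytest.fixture(scope="session")
def small_cohort():
    """A 138-patient synthetic cohort with vitals, fixed seed."""
    return generate_cohort(default_config(n_patients=138, seed=7))
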