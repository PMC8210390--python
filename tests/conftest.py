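import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort shared across tests (seed fixed)."""
    from cardiotox_qmap.synthetic import CohortSpec, make_cohort

    return make_cohort(CohortSpec(seed=7))
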