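import pytest
from hypothesis import HealthCheck, settings

from phexam import SimulationConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_cohort():
    """One synthetic cohort at the study design defaults (52 subjects,
    25 with PH, 3 specialists + 3 generalists, 5 signs x 2 phases)."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def paper_dataset(paper_cohort):
    return paper_cohort[0]
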