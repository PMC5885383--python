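import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def published_specs():
    from opsfuel.synthetic import published_course_specs

    return published_course_specs(with_paf=True)


@pytest.fixture
def small_cohort(published_specs):
    """A deterministic 133-person cohort drawn from the published course specs."""
    from opsfuel.synthetic import SimulationConfig, generate_cohort

    cfg = SimulationConfig(courses=published_specs, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
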