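import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Six short recordings (two per severity stratum), shared across tests."""
    from opibs.synth import SynthConfig, generate_cohort

    cfg = SynthConfig(duration_s=1800.0)
    return generate_cohort(n_per_group=(2, 2, 2), seed=99, base_config=cfg)
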