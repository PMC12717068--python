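import pytest
from hypothesis import HealthCheck, settings

import advrisk as a

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def large_cohort():
    """200k-exam complete cohort under packaged defaults, with its config."""
    cfg = a.default_config(n_women=200_000, seed=1234)
    return cfg, a.generate_complete(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """4k-exam complete cohort for cheap fitting-path tests."""
    cfg = a.default_config(n_women=4_000, seed=99)
    return cfg, a.generate_complete(cfg)
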