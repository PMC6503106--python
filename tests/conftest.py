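import pytest
from hypothesis import HealthCheck, settings

import chemofilm as cf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_params() -> cf.MonodParameters:
    """Kinetic constants of the bundled E. faecalis / TSB scenario."""
    return cf.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def bench_observations():
    """Measured 24-h biofilm assays at D = 0.09, 0.28, 0.81 h^-1."""
    return cf.reference_biofilm_observations()
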