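import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def table1_bottleneck():
    """The bottleneck model at the full-scale point estimates."""
    from sfsdemog.demography import build_bottleneck_model

    return build_bottleneck_model(12_506.0, 534.0, 29_319.0)


@pytest.fixture(scope="session")
def null_model():
    from sfsdemog.demography import build_null_model

    return build_null_model(14_789.0)
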