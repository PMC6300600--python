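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
    return np.random.default_rng(20260101)


@pytest.fixture
def separated_profiles():
    """Four well-separated surrogate profiles over six donor columns."""
    from sourcefind.simulate import SimulationSpec, make_profiles

    spec = SimulationSpec(
        s=4, d=6, true_beta=(0.25, 0.25, 0.25, 0.25), separation=0.9, seed=11
    )
    return make_profiles(spec, np.random.default_rng(11))
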