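import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from smtoptics import PRESETS, SurfaceParams, build_profile

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def flat_profile():
    """A perfectly flat skin-index surface (H = u_h = 0)."""
    return build_profile(
        SurfaceParams(W=100.0, H=0.0, W_V=0.0, u_h=0.0, u_w=1.0, n=1.40),
        samples_per_period=100,
    )


@pytest.fixture(scope="session")
def sample_profiles():
    """Tracer-resolution profiles for the four skin samples and SB6."""
    return {name: build_profile(PRESETS[name])
            for name in ("sample1", "sample2", "sample3", "sample4", "sb6")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
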