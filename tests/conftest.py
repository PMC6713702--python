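import numpy as np
import pytest
from hypothesis import settings

from organoidquant import SceneSpec, generate_scene

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def easy_scene():
    """One small, clean synthetic scene: in-focus, non-overlapping, low noise."""
    spec = SceneSpec(
        width=450,
        height=450,
        n_organoids=3,
        radius_range=(18.0, 45.0),
        overlap_allowed=False,
        noise_sigma=1.0,
        seed=7,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def large_scene():
    """A full-size scene for pipeline-level tests."""
    spec = SceneSpec(
        width=1500,
        height=1125,
        n_organoids=30,
        overlap_allowed=False,
        noise_sigma=2.0,
        seed=3,
    )
    return generate_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
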