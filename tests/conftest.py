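import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_shape():
    """A volume shape large enough for every model family's pooling cascade."""
    return (16, 20, 16)


@pytest.fixture
def tiny_pif_overrides():
    """PIF stage settings valid on the small_shape latent (2x2x2)."""
    return {"patch_counts": (2, 2, 2), "kernel_size": (1, 1, 1),
            "use_overlap": False, "per_patch_pooling": None}
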