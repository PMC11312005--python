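import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctdenoise import PhantomSpec, default_roi_layout, generate_phantom

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 128×128 replica of the phantom at 2 mm spacing (same 25.6 cm FOV)."""
    return PhantomSpec(matrix_size=128, pixel_spacing=2.0)


@pytest.fixture(scope="session")
def small_clean(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_layout(small_spec):
    return default_roi_layout(small_spec, material_roi_size=7, nnps_roi_size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
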