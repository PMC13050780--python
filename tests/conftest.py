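import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from cmbscreen.phantom import PhantomSpec, generate_subject

# Desk-scale phantom geometry used throughout the suite: a 192-px head at
# the reference in-plane resolution, 6 slices at 6.5 mm.
SMALL = dict(dims=(192, 192), n_slices=6)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(n_lesions=6, seed=42, **SMALL)


@pytest.fixture(scope="session")
def subject(small_spec):
    return generate_subject(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
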