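import numpy as np
import pytest

from pqctseg.phantom import PhantomSpec, desk_scale_spec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A noisy desk-scale phantom with exact ground truth (session-cached)."""
    return generate_phantom(desk_scale_spec(seed=11))


@pytest.fixture(scope="session")
def tiny_phantom():
    """A very small phantom for fast network/trainer tests."""
    spec = PhantomSpec(
        n_slices=6,
        in_plane=32,
        outer_radius_mm=0.55,
        cortical_thickness_mm=0.2,
        noise_sd=30.0,
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
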