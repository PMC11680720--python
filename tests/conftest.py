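import numpy as np
import pytest

from onfhgrade import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The reference phantom: 256 px, 60 px head, 20% lesion, low noise."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture()
def small_spec():
    """A 64 px phantom spec for fast training tests."""
    return PhantomSpec(
        image_size=64,
        head_center=(32.0, 32.0),
        head_radii=(16.0, 16.0),
        lesion_fraction=25.0,
        background_texture_scale=4.0,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
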