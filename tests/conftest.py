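import numpy as np
import pytest

from leafquant import LeafSpec, RgbImage, generate

#: compact frame used by unit tests; acceptance tests use the full sensor frame
SMALL = dict(height=256, width=320)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def uniform_rgb(r, g, b, shape=(8, 8), bit_depth=8):
    """Uniform-colour image helper."""
    h, w = shape
    return RgbImage(
        np.full((h, w), r, dtype=np.int64),
        np.full((h, w), g, dtype=np.int64),
        np.full((h, w), b, dtype=np.int64),
        bit_depth,
    )


@pytest.fixture(scope="session")
def clean_leaf():
    """Symptom-free small leaf on a white panel, with ground truth."""
    return generate(LeafSpec(seed=11, **SMALL))


@pytest.fixture(scope="session")
def necrotic_leaf():
    return generate(LeafSpec(seed=12, necrotic_fraction=0.10, **SMALL))


@pytest.fixture(scope="session")
def spotted_leaf():
    return generate(LeafSpec(seed=13, spot_fraction=0.08, **SMALL))


@pytest.fixture(scope="session")
def backlit_leaf():
    return generate(LeafSpec(seed=14, lighting="backlit", vein_depth=4, **SMALL))
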