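import numpy as np
import pytest

from uwfchoroid.geometry import EyeModel
from uwfchoroid.synthetic import SyntheticImageSpec, generate_image_pair


@pytest.fixture(scope="session")
def small_model() -> EyeModel:
    """Fine-pitch model covering ~6 mm radius, for geometry closed-form checks."""
    return EyeModel(grid_shape=(257, 257), pixel_pitch=0.05, fovea_pixel=(128, 128))


@pytest.fixture(scope="session")
def synthetic_pair():
    """One default synthetic FA/ICGA pair, shared across tests (deterministic)."""
    return generate_image_pair(SyntheticImageSpec(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
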