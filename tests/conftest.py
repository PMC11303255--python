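import numpy as np
import pytest

from pnnquant.synth import NetSpec


@pytest.fixture(scope="session")
def small_spec() -> NetSpec:
    """A small, fast net geometry for unit tests (full-size cohorts are
    exercised in the acceptance tests)."""
    return NetSpec(contour_radius=4.0, n_holes=8, pixel_size=0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
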