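import numpy as np
import pytest

from scoliometry.imaging import RegionBox
from scoliometry.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_factory():
    """Phantom image + truth + full-image ROI for a given spec."""

    def make(**kwargs):
        spec = PhantomSpec(**kwargs)
        image, truth = generate_phantom(spec)
        roi = RegionBox(0, spec.width - 1, 0, spec.height - 1)
        return spec, image, truth, roi

    return make
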