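import numpy as np
import pytest

from alansim.fixtures import make_toy_lid, make_toy_spectrum
from alansim.photometry import build_direction_sampler


@pytest.fixture
def rng():
    return np.random.default_rng(20240228)


@pytest.fixture
def isotropic_lid():
    return make_toy_lid("isotropic")


@pytest.fixture
def isotropic_sampler(isotropic_lid):
    return build_direction_sampler(isotropic_lid)


@pytest.fixture
def flat_spectrum():
    return make_toy_spectrum("flat")


class FixedRng:
    """Deterministic uniform source cycling through supplied values."""

    def __init__(self, values):
        self.values = list(values)
        self.i = 0

    def random(self, size=None):
        if size is not None:
            return np.array([self.random() for _ in range(int(size))])
        v = self.values[self.i % len(self.values)]
        self.i += 1
        return v

    def uniform(self, low=0.0, high=1.0, size=None):
        return low + (high - low) * self.random(size)

    def open_unit(self):
        return max(self.random(), 1e-12)


@pytest.fixture
def fixed_rng_factory():
    return FixedRng
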