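import numpy as np
import pytest

from leup.core import ConeMosaicStats, load_fixture

#: Published chicken cone occurrence proportions (green, red, blue, violet, double).
CHICKEN_P = np.array([0.204, 0.160, 0.133, 0.094, 0.409])
#: Published per-type NND standard deviations, micrometres (same order).
CHICKEN_SIGMA = np.array([1.248, 1.548, 1.729, 2.292, 0.948])
#: Published mean sensing radii (micrometres) and hyperuniformity exponents,
#: keyed by cone type.
CHICKEN_RADII = {"green": 1.426, "red": 2.006, "blue": 2.288, "violet": 3.553, "double": 0.786}
CHICKEN_EXPONENTS = {"green": 1.247, "red": 1.256, "blue": 1.322, "violet": 1.308, "double": 0.440}


@pytest.fixture(scope="session")
def chicken() -> ConeMosaicStats:
    return load_fixture("kram2010_chicken")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
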