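import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from origametry import synthetic_data as sd


@pytest.fixture(scope="session")
def duplex16():
    """Ideal 16-bp duplex: (topology, frame, ground truth)."""
    return sd.make_duplex(16, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng):
    """Uniform random proper rotation and a translation."""
    from origametry.geometry import random_rotation

    return random_rotation(rng), rng.normal(scale=10.0, size=3)
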