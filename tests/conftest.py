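import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from chronotopo import synthetic_data as sd
from chronotopo.prf_model import StimulusSpec


@pytest.fixture(scope="session")
def stim() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture(scope="session")
def small_patch() -> sd.SurfacePatch:
    """10x10 unit lattice, one ROI."""
    return sd.make_patch(10, 10, 1.0)


@pytest.fixture(scope="session")
def lattice_20() -> sd.SurfacePatch:
    """20x20 lattice with 1 mm spacing."""
    return sd.make_patch(20, 20, 1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
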