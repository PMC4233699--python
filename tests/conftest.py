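import numpy as np
import pytest

from spiralox import SpiralGeometry


@pytest.fixture
def study_geom() -> SpiralGeometry:
    """The construct geometry: 80 um inner diameter, 80 um sheet, 9 turns."""
    return SpiralGeometry(D0=80.0, h=80.0, N=9)


@pytest.fixture
def wide_geom() -> SpiralGeometry:
    """A 40-turn spiral whose radial span holds a multi-layer cohort."""
    return SpiralGeometry(D0=80.0, h=80.0, N=40)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
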