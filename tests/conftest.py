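import numpy as np
import pytest

from popbias import DecodeGrid, NoiseSpec, TuningModel, build_population


@pytest.fixture
def default_pop():
    """The canonical 4-neuron rectified-cosine population (A=1, c=-0.1)."""
    return build_population(4)


@pytest.fixture
def gaussian_noise():
    return NoiseSpec("gaussian", sigma=0.1)


@pytest.fixture
def narrow_pop():
    """Narrow tuning (c=0.1): near a preferred angle only one neuron is active."""
    return build_population(4, tuning=TuningModel("rectified_cosine", threshold=0.1))


@pytest.fixture
def coarse_grid():
    """Coarser decode grid for unit tests where speed matters more than 1e-4 rad."""
    return DecodeGrid(2000)


@pytest.fixture
def pure_cosine_pop():
    return build_population(4, tuning=TuningModel("rectified_cosine", threshold=-1.0))
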