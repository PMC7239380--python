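import numpy as np
import pytest

from spiraflux import FlutterSchedule, TrachealModel, WaterModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def silkworm_schedule():
    """Flutter schedule of the Saturniid silkworm case: 0.5 s open bouts
    separated by 5 s closed bouts (p = 1/11, r = 2.2 /s)."""
    return FlutterSchedule.from_durations(0.5, 5.0)


@pytest.fixture
def unit_tube():
    """1 cm tube with default oxygen physics."""
    return TrachealModel(L=1.0)


@pytest.fixture
def water_k1():
    """Water physics with k = 1 /s and a unit vapour gradient."""
    return WaterModel(k=1.0)
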