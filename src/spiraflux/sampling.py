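"""Random physiological parameter sets for property-based testing.

Ranges span the insect case studies: tracheal lengths from fractions of a
millimetre to a couple of centimetres, flutter rates from sub-0.1/s (pine
weevil) to tens per second (Cataglyphis), open fractions from a few percent
to one half, and wall transfer rates covering both the low-loss and
p-proportional water regimes.
"""

from __future__ import annotations

import numpy as np

from .model import D_OXYGEN, D_WATER, FlutterSchedule, TrachealModel, WaterModel

__all__ = [
    "random_tracheal_model",
    "random_schedule",
    "random_water_model",
]


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def random_tracheal_model(
    rng: np.random.Generator, with_convection: bool = False
) -> TrachealModel:
    """Draw a tracheal geometry within physiological ranges."""
    L = _loguniform(rng, 0.05, 2.0)
    a = _loguniform(rng, 0.005, 0.1)
    v = -_loguniform(rng, 1e-3, 0.5) if with_convection else 0.0
    return TrachealModel(L=L, a=a, D=D_OXYGEN, A=1.0, v=v)


def random_schedule(rng: np.random.Generator) -> FlutterSchedule:
    """Draw a flutter schedule: p in [0.02, 0.5], r in [0.05, 50] 1/s."""
    p = float(rng.uniform(0.02, 0.5))
    r = _loguniform(rng, 0.05, 50.0)
    return FlutterSchedule(p=p, r=r)


def random_water_model(rng: np.random.Generator) -> WaterModel:
    """Draw water physics: k spanning both loss regimes, I > A_w >= 0."""
    k = _loguniform(rng, 1e-3, 10.0)
    A_w = float(rng.uniform(0.0, 0.5))
    I = A_w + float(rng.uniform(0.1, 1.0))
    return WaterModel(k=k, D_w=D_WATER, I=I, A_w=A_w)
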