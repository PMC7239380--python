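"""Domain types and closed-form results for gas exchange through a fluttering spiracle.

Insects exhibiting discontinuous gas exchange alternate open, closed, and
*flutter* phases; during flutter the spiracle opens and closes rapidly and
stochastically.  The tracheal system is modelled as a one-dimensional tube of
length ``L`` (cm): the tracheole end at ``x = 0`` absorbs oxygen perfectly
(``c(0, t) = 0``) and the spiracle end at ``x = L`` switches between a
Dirichlet condition ``c(L, t) = A`` (open, ambient concentration ``A``) and a
no-flux condition (closed).  Open and closed bout durations are independent
exponential random variables with means ``d_o`` and ``d_c``, equivalently
described by the open fraction ``p = d_o/(d_o + d_c)`` and the flutter rate
``r = (d_o + d_c)/(d_o d_c)``.

The stationary expected concentration under this switching is linear,
``c_flutter(x) = f A x / L``, where the *flutter factor*

    f(p, s) = [1 + ((1 - p)/p) tanh(sqrt(s))/sqrt(s)]^-1,   s = r L^2 / D,

is the ratio of mean flutter-phase uptake to the always-open uptake
``U_open = pi a^2 D A / L``.  The *respiratory gain* ``G = f/p`` measures the
fold increase of uptake over the slow-fluttering limit ``p U_open``.

A reaction-diffusion analogue describes water vapour, with transfer through
the tracheal wall at rate ``k`` toward the interior equilibrium level ``I``;
the always-open steady loss through the spiracle is
``W_open = (I - A_w) pi a^2 sqrt(k D_w) tanh(sqrt(k L^2 / D_w))``.

Units are CGS + seconds throughout: lengths in cm, diffusivities in cm^2/s,
rates in 1/s.  Concentrations are in arbitrary units (they cancel in the
dimensionless factors f, G, f_w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "D_OXYGEN",
    "D_WATER",
    "DEFAULT_RADIUS",
    "TrachealModel",
    "FlutterSchedule",
    "WaterModel",
    "CyclePhases",
    "durations_to_rates",
    "rates_to_durations",
    "flutter_factor",
    "respiratory_gain",
    "open_uptake",
    "open_profile",
    "flutter_mean_profile",
    "cycle_uptake",
    "water_open_loss",
]

#: Diffusion coefficient of oxygen in air, cm^2/s.
D_OXYGEN = 0.176
#: Diffusion coefficient of water vapour in air, cm^2/s.
D_WATER = 0.282
#: Default tracheal tube radius, cm.  It cancels in f, G and f_w; only the
#: absolute uptake and loss rates depend on it.
DEFAULT_RADIUS = 0.05


def _tanh_sqrt_ratio(s: float) -> float:
    """tanh(sqrt(s))/sqrt(s), with a series fallback near the removable
    singularity at s = 0 (tanh(x)/x = 1 - x^2/3 + O(x^4))."""
    if s < 1e-12:
        return 1.0 - s / 3.0
    root = math.sqrt(s)
    return math.tanh(root) / root


@dataclass(frozen=True)
class TrachealModel:
    """Tube geometry and oxygen physics.

    Parameters
    ----------
    L : float
        Tracheal length, cm (spiracle at ``x = L``, tracheole at ``x = 0``).
    a : float
        Tube radius, cm.
    D : float
        Oxygen diffusion coefficient, cm^2/s.
    A : float
        Ambient oxygen concentration, arbitrary units.
    v : float
        Convection velocity, cm/s.  ``v < 0`` is inward bulk flow (toward the
        tracheole); the default 0 recovers the pure-diffusion model.
    """

    L: float
    a: float = DEFAULT_RADIUS
    D: float = D_OXYGEN
    A: float = 1.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"tracheal length L must be positive, got {self.L}")
        if not self.a > 0:
            raise ValueError(f"tube radius a must be positive, got {self.a}")
        if not self.D > 0:
            raise ValueError(f"diffusion coefficient D must be positive, got {self.D}")
        if self.A < 0:
            raise ValueError(f"ambient concentration A must be >= 0, got {self.A}")

    @property
    def diffusion_time(self) -> float:
        """L^2/D, the spiracle-to-tracheole diffusion timescale, s."""
        return self.L**2 / self.D

    @property
    def peclet(self) -> float:
        """Dimensionless convection number V = vL/D."""
        return self.v * self.L / self.D

    @property
    def cross_section(self) -> float:
        """pi a^2, cm^2."""
        return math.pi * self.a**2


@dataclass(frozen=True)
class FlutterSchedule:
    """Stochastic spiracle dynamics during the flutter phase.

    ``p`` is the stationary fraction of time open (0 < p <= 1) and ``r`` the
    flutter rate (1/s).  Mean bout durations follow from the exponential bout
    law: ``d_o = 1/((1-p) r)`` and ``d_c = 1/(p r)``.
    """

    p: float
    r: float

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"open fraction p must be in (0, 1], got {self.p}")
        if not self.r > 0:
            raise ValueError(f"flutter rate r must be positive, got {self.r}")

    @classmethod
    def from_durations(cls, d_open: float, d_closed: float) -> "FlutterSchedule":
        p, r = durations_to_rates(d_open, d_closed)
        return cls(p=p, r=r)

    @property
    def d_open(self) -> float:
        """Mean open bout duration, s (infinite when p = 1)."""
        if self.p == 1.0:
            return math.inf
        return 1.0 / ((1.0 - self.p) * self.r)

    @property
    def d_closed(self) -> float:
        """Mean closed bout duration, s."""
        return 1.0 / (self.p * self.r)

    def switching_number(self, L: float, D: float) -> float:
        """Dimensionless switching rate s = r L^2 / D."""
        return self.r * L**2 / D


@dataclass(frozen=True)
class WaterModel:
    """Water-vapour physics of the tracheal tube.

    ``k`` (1/s) is the transfer rate of water through the tracheal wall,
    relaxing the vapour concentration toward the interior equilibrium level
    ``I``; ``A_w`` is the ambient vapour concentration (same arbitrary units,
    ``I >= A_w`` in the outward-loss regime).
    """

    k: float
    D_w: float = D_WATER
    I: float = 1.0
    A_w: float = 0.0

    def __post_init__(self) -> None:
        if not self.D_w > 0:
            raise ValueError(f"water diffusivity D_w must be positive, got {self.D_w}")
        if self.k < 0:
            raise ValueError(f"wall transfer rate k must be >= 0, got {self.k}")
        if not self.I >= self.A_w >= 0:
            raise ValueError(
                f"require I >= A_w >= 0 (outward loss regime), got I={self.I}, A_w={self.A_w}"
            )

    def sigma(self, r: float, L: float) -> float:
        """Dimensionless flutter rate sigma = r L^2 / D_w."""
        return r * L**2 / self.D_w

    def kappa(self, L: float) -> float:
        """Dimensionless wall transfer rate kappa = k L^2 / D_w."""
        return self.k * L**2 / self.D_w


@dataclass(frozen=True)
class CyclePhases:
    """Fractions of the discontinuous gas-exchange cycle spent fluttering
    (``p_f``), closed (``p_c``) and open (``p_o``).  Note ``p_o`` is distinct
    from the within-flutter open fraction ``p``."""

    p_f: float
    p_c: float
    p_o: float

    def __post_init__(self) -> None:
        for name in ("p_f", "p_c", "p_o"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        total = self.p_f + self.p_c + self.p_o
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase fractions must sum to 1, got {total}")


def durations_to_rates(d_open: float, d_closed: float) -> tuple[float, float]:
    """Convert mean open/closed bout durations (s) to (p, r).

    p = d_o/(d_o + d_c) and r = (d_o + d_c)/(d_o d_c).
    """
    if not d_open > 0:
        raise ValueError(f"mean open duration must be positive, got {d_open}")
    if not d_closed > 0:
        raise ValueError(f"mean closed duration must be positive, got {d_closed}")
    p = d_open / (d_open + d_closed)
    r = (d_open + d_closed) / (d_open * d_closed)
    return p, r


def rates_to_durations(p: float, r: float) -> tuple[float, float]:
    """Inverse of :func:`durations_to_rates`: d_o = 1/((1-p)r), d_c = 1/(pr)."""
    if not 0 < p < 1:
        raise ValueError(f"open fraction p must be in (0, 1) to invert, got {p}")
    if not r > 0:
        raise ValueError(f"flutter rate r must be positive, got {r}")
    return 1.0 / ((1.0 - p) * r), 1.0 / (p * r)


def flutter_factor(p: float, s: float) -> float:
    """Flutter factor f(p, s) = [1 + ((1-p)/p) tanh(sqrt(s))/sqrt(s)]^-1.

    ``s = r L^2 / D`` compares the flutter rate to the diffusion time.
    ``f`` lies in (0, 1]; f -> p as s -> 0 and f -> 1 as s -> infinity, so a
    rapidly fluttering insect takes up nearly as much oxygen as one whose
    spiracle never closes, whatever the open fraction p.
    """
    if not 0 < p <= 1:
        raise ValueError(f"open fraction p must be in (0, 1], got {p}")
    if not s > 0:
        raise ValueError(f"dimensionless switching rate s must be positive, got {s}")
    if p == 1.0:
        return 1.0
    return 1.0 / (1.0 + (1.0 - p) / p * _tanh_sqrt_ratio(s))


def respiratory_gain(p: float, s: float) -> float:
    """Respiratory gain G = f(p, s)/p, the fold increase of flutter-phase
    uptake over the slow-switching limit p*U_open.  G >= 1, rising from 1
    (s -> 0) to 1/p (s -> infinity)."""
    return flutter_factor(p, s) / p


def open_uptake(model: TrachealModel) -> float:
    """Oxygen uptake per unit time with the spiracle permanently open,
    U_open = pi a^2 D A / L (pure diffusion; requires v = 0)."""
    if model.v != 0.0:
        raise ValueError("open_uptake requires v = 0; use open_uptake_convective")
    return model.cross_section * model.D * model.A / model.L


def open_profile(x, model: TrachealModel):
    """Always-open steady concentration profile c_open(x) = A x / L.

    ``x`` may be a scalar or array, each entry within [0, L]."""
    import numpy as np

    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > model.L):
        raise ValueError("positions x must lie within [0, L]")
    out = model.A * x / model.L
    return out if out.ndim else float(out)


def flutter_mean_profile(x, model: TrachealModel, f: float):
    """Stationary expected concentration during flutter,
    c_flutter(x) = f * A x / L."""
    if not 0 < f <= 1:
        raise ValueError(f"flutter factor f must be in (0, 1], got {f}")
    out = open_profile(x, model)
    import numpy as np

    return f * np.asarray(out) if np.ndim(out) else f * out


def cycle_uptake(phases: CyclePhases, f: float, u_open: float) -> float:
    """Mean oxygen uptake over the whole open/closed/flutter cycle:
    (f p_f + p_o) U_open, the closed-phase uptake being ~0."""
    if not 0 < f <= 1:
        raise ValueError(f"flutter factor f must be in (0, 1], got {f}")
    return (f * phases.p_f + phases.p_o) * u_open


def water_open_loss(water: WaterModel, L: float, a: float = DEFAULT_RADIUS) -> float:
    """Always-open steady water loss through the spiracle,
    W_open = (I - A_w) pi a^2 sqrt(k D_w) tanh(sqrt(k L^2 / D_w)).

    Zero when k = 0 (no wall transfer, interior equilibrates with ambient) or
    when I = A_w (no gradient); saturates at (I - A_w) pi a^2 sqrt(k D_w) for
    kappa = k L^2/D_w >> 1.
    """
    if not L > 0:
        raise ValueError(f"tracheal length L must be positive, got {L}")
    if not a > 0:
        raise ValueError(f"tube radius a must be positive, got {a}")
    if water.k == 0.0:
        return 0.0
    kappa = water.kappa(L)
    return (
        (water.I - water.A_w)
        * math.pi
        * a**2
        * math.sqrt(water.k * water.D_w)
        * math.tanh(math.sqrt(kappa))
    )
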