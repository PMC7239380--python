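"""Headless figure generation.

Four figure analogues, one per result of the model:

1. relaxation profiles after spiracle closure (why rapid fluttering barely
   reduces tracheole uptake);
2. flutter factor and respiratory gain versus flutter rate for several open
   fractions;
3. water flutter factor versus wall transfer rate for selected insects, with
   the p reference lines;
4. respiratory gain surface over tracheal length and flutter rate.

All routines run with the Agg backend and write SVG or PNG files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .casebook import InsectCase, load_cases, sweep_flutter_factor, sweep_gain, sweep_water_factor
from .model import D_OXYGEN, D_WATER, TrachealModel
from .sim import closed_relaxation

__all__ = [
    "relaxation_figure",
    "flutter_factor_figure",
    "water_factor_figure",
    "gain_surface_figure",
    "all_figures",
]


def relaxation_figure(
    out: str | Path,
    model: TrachealModel | None = None,
    t_short_frac: float = 0.05,
    t_long_frac: float = 0.5,
    n_x: int = 201,
) -> Path:
    """Oxygen profiles before and after spiracle closure.

    ``t_short_frac``/``t_long_frac`` are the two closure times as fractions
    of the diffusion time L^2/D (defaults chosen to separate the "barely
    changed slope" and "collapsed slope" regimes; the exact values are
    illustrative only).
    """
    model = model or TrachealModel(L=1.0)
    tau = model.diffusion_time
    times = [t_short_frac * tau, t_long_frac * tau]
    profiles = closed_relaxation(model, times, n_x=n_x)
    x = np.linspace(0.0, model.L, n_x)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(x, model.A * x / model.L, "b-", label="open a long time")
    ax.plot(x, profiles[0], "k-", label=f"closed for t1 = {times[0]:.3g} s")
    ax.plot(x, profiles[1], "r-", label=f"closed for t2 = {times[1]:.3g} s")
    ax.set_xlabel("x (cm), tracheole at 0, spiracle at L")
    ax.set_ylabel("oxygen concentration")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out


def flutter_factor_figure(
    out: str | Path,
    p_values=(0.02, 0.2, 0.5),
    r_values=None,
    L: float = 1.0,
    D: float = D_OXYGEN,
) -> Path:
    """Flutter factor and respiratory gain versus flutter rate."""
    if r_values is None:
        r_values = np.logspace(-2, 2, 80)
    curves = sweep_flutter_factor(p_values, r_values, L=L, D=D)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    for p, sub in curves.groupby("p"):
        ax1.semilogx(sub["r_per_s"], sub["f"], label=f"p = {p:g}")
        ax2.semilogx(sub["r_per_s"], sub["gain"], label=f"p = {p:g}")
    ax1.set_xlabel("flutter rate r (1/s)")
    ax1.set_ylabel("flutter factor f")
    ax2.set_xlabel("flutter rate r (1/s)")
    ax2.set_ylabel("respiratory gain G = f/p")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out


def water_factor_figure(
    out: str | Path,
    cases: list[InsectCase] | None = None,
    k_values=None,
    D_w: float = D_WATER,
    n_grid: int = 200,
) -> Path:
    """Water flutter factor versus wall transfer rate with p reference lines."""
    if cases is None:
        bundled = load_cases()
        cases = [bundled[0], bundled[1]]  # silkworm and Cataglyphis abdominal
    if k_values is None:
        k_values = np.logspace(-3, 2, 25)
    curves = sweep_water_factor(cases, k_values, D_w=D_w, n_grid=n_grid)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, sub in curves.groupby("case", sort=False):
        (line,) = ax.semilogx(sub["k_per_s"], sub["f_w"], label=name)
        ax.axhline(sub["p"].iloc[0], color=line.get_color(), ls="--", lw=0.8)
    ax.set_xlabel("water transfer rate k (1/s)")
    ax.set_ylabel("water flutter factor $f_w$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out


def gain_surface_figure(
    out: str | Path,
    p: float = 0.2,
    r_values=None,
    L_values=None,
    D: float = D_OXYGEN,
) -> Path:
    """Respiratory gain surface over tracheal length and flutter rate."""
    if r_values is None:
        r_values = np.logspace(-2, 2, 60)
    if L_values is None:
        L_values = np.linspace(0.05, 2.0, 60)
    surface = sweep_gain(p, r_values, L_values, D=D)
    fig, ax = plt.subplots(figsize=(5, 3.8))
    mesh = ax.pcolormesh(
        surface.columns, surface.index, surface.values, shading="auto"
    )
    ax.set_xscale("log")
    ax.set_xlabel("flutter rate r (1/s)")
    ax.set_ylabel("tracheal length L (cm)")
    fig.colorbar(mesh, ax=ax, label=f"respiratory gain G (p = {p:g})")
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out)
    plt.close(fig)
    return out


def all_figures(out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Write all four figures into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [
        relaxation_figure(out_dir / f"relaxation_profiles.{fmt}"),
        flutter_factor_figure(out_dir / f"flutter_factor_gain.{fmt}"),
        water_factor_figure(out_dir / f"water_flutter_factor.{fmt}"),
        gain_surface_figure(out_dir / f"gain_surface.{fmt}"),
    ]
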