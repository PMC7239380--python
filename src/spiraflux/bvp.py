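"""Two-mode boundary-value problems for stationary expected concentrations.

The randomly switching boundary condition makes the concentration a
piecewise-deterministic Markov process.  Splitting the stationary expectation
by spiracle state,

    u0(x) = lim E[c(x, t) 1{open}],   u1(x) = lim E[c(x, t) 1{closed}],

gives a coupled linear two-point boundary-value problem: each component obeys
the (advection-)diffusion operator plus exchange terms at the mode-switching
rates 1/d_o = (1-p) r (open -> closed) and 1/d_c = p r (closed -> open),

    0 = D u0'' - v u0' - (1-p) r u0 + p r u1,
    0 = D u1'' - v u1' + (1-p) r u0 - p r u1,

with u0(0) = u1(0) = 0, u0(L) = p A and the convective no-flux condition
-D u1'(L) + v u1(L) = 0.  The stationary expected concentration is
u0 + u1, and the flutter factor follows from the flux at the tracheole.

The analogous water-vapour system adds the wall-transfer reaction: the source
k(I - w) contributes k(p I - w0) to the open component and k((1-p) I - w1) to
the closed one (the interior level I is weighted by the stationary mode
probability), with reflecting tracheole end w0'(0) = w1'(0) = 0, open-mode
Dirichlet w0(L) = p A_w and closed-mode no-flux w1'(L) = 0.

These solvers are the normative route to the flutter factor with convection
and to the water flutter factor f_w = W_flutter/W_open; the closed forms for
those two quantities are deliberately not reimplemented here.

Discretization: second-order central differences on a uniform grid; Neumann
and Robin conditions through ghost nodes (second order); boundary fluxes by
one-sided three-point differences; a cell-Peclet guard (|v| h / D < 2)
refines the grid automatically so the central convection stencil stays an
M-matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import (
    FlutterSchedule,
    TrachealModel,
    WaterModel,
    open_uptake,
    water_open_loss,
)

__all__ = [
    "TwoModeSolution",
    "solve_two_mode_oxygen",
    "flutter_factor_bvp",
    "open_uptake_convective",
    "solve_two_mode_water",
    "water_flutter_factor_bvp",
]


@dataclass(frozen=True)
class TwoModeSolution:
    """Discrete solution of a two-mode stationary-expectation BVP.

    ``u0`` carries the open-spiracle boundary condition, ``u1`` the closed
    one; ``u0 + u1`` (:attr:`total`) is the stationary expected
    concentration.  ``residual`` is the max-norm residual of the discretized
    operator at the solution.
    """

    x_grid: np.ndarray
    u0: np.ndarray
    u1: np.ndarray
    mode_labels: tuple[str, str] = ("open", "closed")
    residual: float = 0.0

    @property
    def total(self) -> np.ndarray:
        return self.u0 + self.u1


def _one_sided_derivative(u: np.ndarray, h: float, *, at_start: bool) -> float:
    """Second-order three-point one-sided first derivative."""
    if at_start:
        return (-3.0 * u[0] + 4.0 * u[1] - u[2]) / (2.0 * h)
    return (3.0 * u[-1] - 4.0 * u[-2] + u[-3]) / (2.0 * h)


def _peclet_refine(n_grid: int, L: float, v: float, D: float) -> int:
    """Smallest grid (>= n_grid intervals) satisfying |v| h / D < 2."""
    if v == 0.0:
        return n_grid
    n_min = int(math.ceil(abs(v) * L / (2.0 * D))) + 1
    return max(n_grid, n_min)


def _solve(A: sp.spmatrix, b: np.ndarray) -> tuple[np.ndarray, float]:
    sol = spla.spsolve(sp.csr_matrix(A), b)
    if not np.all(np.isfinite(sol)):
        raise RuntimeError(
            "two-mode BVP produced a non-finite solution; the discretization "
            "is singular for these parameters"
        )
    residual = float(np.max(np.abs(A @ sol - b)))
    scale = max(1.0, float(np.max(np.abs(b))))
    if residual > 1e-8 * scale:
        raise RuntimeError(
            f"two-mode BVP residual {residual:.3e} exceeds tolerance; "
            "parameters may be degenerate"
        )
    return sol, residual


def solve_two_mode_oxygen(
    model: TrachealModel, schedule: FlutterSchedule, n_grid: int = 400
) -> TwoModeSolution:
    """Solve the coupled stationary-expectation system for oxygen.

    ``n_grid`` is the number of grid intervals (>= 50); it is refined
    automatically if needed to satisfy the cell-Peclet guard.
    """
    if n_grid < 50:
        raise ValueError(f"n_grid must be >= 50, got {n_grid}")
    n_grid = _peclet_refine(n_grid, model.L, model.v, model.D)
    n = n_grid  # intervals; n + 1 points per component
    h = model.L / n
    D, v, p, r, A = model.D, model.v, schedule.p, schedule.r, model.A
    rate_oc = (1.0 - p) * r  # open -> closed, 1/d_o
    rate_co = p * r  # closed -> open, 1/d_c

    N = n + 1
    M = sp.lil_matrix((2 * N, 2 * N))
    b = np.zeros(2 * N)
    i0 = lambda j: j  # noqa: E731 - index of u0_j
    i1 = lambda j: N + j  # noqa: E731 - index of u1_j

    diff = D / h**2
    adv = v / (2.0 * h)

    # u0: Dirichlet at both ends.
    M[i0(0), i0(0)] = 1.0
    b[i0(0)] = 0.0
    M[i0(n), i0(n)] = 1.0
    b[i0(n)] = p * A
    for j in range(1, n):
        M[i0(j), i0(j - 1)] = diff + adv
        M[i0(j), i0(j)] = -2.0 * diff - rate_oc
        M[i0(j), i0(j + 1)] = diff - adv
        M[i0(j), i1(j)] = rate_co

    # u1: Dirichlet at 0, convective no-flux (-D u1' + v u1 = 0) at L via a
    # ghost node u1_{n+1} = u1_{n-1} + 2 h (v/D) u1_n.
    M[i1(0), i1(0)] = 1.0
    b[i1(0)] = 0.0
    for j in range(1, n):
        M[i1(j), i1(j - 1)] = diff + adv
        M[i1(j), i1(j)] = -2.0 * diff - rate_co
        M[i1(j), i1(j + 1)] = diff - adv
        M[i1(j), i0(j)] = rate_oc
    M[i1(n), i1(n - 1)] = 2.0 * diff
    M[i1(n), i1(n)] = -2.0 * diff + 2.0 * v / h - v**2 / D - rate_co
    M[i1(n), i0(n)] = rate_oc

    sol, residual = _solve(M, b)
    x = np.linspace(0.0, model.L, N)
    return TwoModeSolution(x_grid=x, u0=sol[:N], u1=sol[N:], residual=residual)


def open_uptake_convective(model: TrachealModel) -> float:
    """Always-open uptake with convection, U_open = pi a^2 A v / (e^{vL/D} - 1).

    Positive for either sign of v, larger for inward flow (v < 0), and tending
    to the diffusive value pi a^2 D A / L as v -> 0 (evaluated by series for
    |V| < 1e-6 to avoid 0/0).
    """
    V = model.peclet
    if model.v == 0.0:
        return open_uptake(model)
    base = model.cross_section * model.A * model.D / model.L
    if abs(V) < 1e-6:
        # V/(e^V - 1) = 1 - V/2 + V^2/12 + O(V^4)
        return base * (1.0 - V / 2.0 + V**2 / 12.0)
    return base * V / math.expm1(V)


def flutter_factor_bvp(
    model: TrachealModel, schedule: FlutterSchedule, n_grid: int = 400
) -> float:
    """Flutter factor from the two-mode BVP: f = U_flutter / U_open, with
    U_flutter = pi a^2 [D (u0' + u1')(0) - v (u0 + u1)(0)] (the last term
    vanishes under the absorbing tracheole condition)."""
    sol = solve_two_mode_oxygen(model, schedule, n_grid=n_grid)
    h = sol.x_grid[1] - sol.x_grid[0]
    slope = _one_sided_derivative(sol.total, h, at_start=True)
    u_flutter = model.cross_section * model.D * slope
    u_open = open_uptake_convective(model) if model.v != 0.0 else open_uptake(model)
    return float(u_flutter / u_open)


def solve_two_mode_water(
    water: WaterModel,
    schedule: FlutterSchedule,
    L: float,
    n_grid: int = 400,
) -> TwoModeSolution:
    """Solve the coupled stationary-expectation system for water vapour."""
    if n_grid < 50:
        raise ValueError(f"n_grid must be >= 50, got {n_grid}")
    if not L > 0:
        raise ValueError(f"tracheal length L must be positive, got {L}")
    n = n_grid
    h = L / n
    Dw, k, I, Aw = water.D_w, water.k, water.I, water.A_w
    p, r = schedule.p, schedule.r
    rate_oc = (1.0 - p) * r
    rate_co = p * r

    N = n + 1
    M = sp.lil_matrix((2 * N, 2 * N))
    b = np.zeros(2 * N)
    i0 = lambda j: j  # noqa: E731
    i1 = lambda j: N + j  # noqa: E731
    diff = Dw / h**2

    # w0: Neumann at 0 (ghost w0_{-1} = w0_1), Dirichlet at L.
    M[i0(0), i0(1)] = 2.0 * diff
    M[i0(0), i0(0)] = -2.0 * diff - k - rate_oc
    M[i0(0), i1(0)] = rate_co
    b[i0(0)] = -k * p * I
    for j in range(1, n):
        M[i0(j), i0(j - 1)] = diff
        M[i0(j), i0(j)] = -2.0 * diff - k - rate_oc
        M[i0(j), i0(j + 1)] = diff
        M[i0(j), i1(j)] = rate_co
        b[i0(j)] = -k * p * I
    M[i0(n), i0(n)] = 1.0
    b[i0(n)] = p * Aw

    # w1: Neumann at both ends (ghosts).
    M[i1(0), i1(1)] = 2.0 * diff
    M[i1(0), i1(0)] = -2.0 * diff - k - rate_co
    M[i1(0), i0(0)] = rate_oc
    b[i1(0)] = -k * (1.0 - p) * I
    for j in range(1, n):
        M[i1(j), i1(j - 1)] = diff
        M[i1(j), i1(j)] = -2.0 * diff - k - rate_co
        M[i1(j), i1(j + 1)] = diff
        M[i1(j), i0(j)] = rate_oc
        b[i1(j)] = -k * (1.0 - p) * I
    M[i1(n), i1(n - 1)] = 2.0 * diff
    M[i1(n), i1(n)] = -2.0 * diff - k - rate_co
    M[i1(n), i0(n)] = rate_oc
    b[i1(n)] = -k * (1.0 - p) * I

    sol, residual = _solve(M, b)
    x = np.linspace(0.0, L, N)
    return TwoModeSolution(x_grid=x, u0=sol[:N], u1=sol[N:], residual=residual)


def water_flutter_factor_bvp(
    water: WaterModel,
    schedule: FlutterSchedule,
    L: float,
    n_grid: int = 400,
) -> float:
    """Water flutter factor f_w = W_flutter / W_open from the two-mode BVP.

    W_flutter is the outward diffusive flux of the open-mode component at the
    spiracle, -pi a^2 D_w w0'(L) (flux occurs only while the spiracle is
    open; the closed component carries zero flux at L by construction).  The
    tube radius cancels in the ratio.  f_w is independent of I and A_w and
    tends to p as kappa = k L^2/D_w grows.
    """
    if water.k == 0.0:
        raise ValueError(
            "water flutter factor is undefined at k = 0 (always-open loss "
            "W_open vanishes)"
        )
    if water.I == water.A_w:
        raise ValueError(
            "water flutter factor is undefined when I = A_w (no vapour "
            "gradient, W_open = 0)"
        )
    sol = solve_two_mode_water(water, schedule, L, n_grid=n_grid)
    h = sol.x_grid[1] - sol.x_grid[0]
    slope = _one_sided_derivative(sol.u0, h, at_start=False)
    w_flutter = -water.D_w * slope  # outward flux per unit cross-section
    kappa = water.kappa(L)
    w_open = (water.I - water.A_w) * math.sqrt(water.k * water.D_w) * math.tanh(
        math.sqrt(kappa)
    )
    return float(w_flutter / w_open)
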