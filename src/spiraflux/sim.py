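"""Monte-Carlo simulation of diffusion with a randomly switching boundary.

Each realization integrates the (advection-)diffusion equation (or the
water-vapour reaction-diffusion equation) on a uniform spatial grid while the
spiracle-end boundary condition switches between open and closed at
exponentially distributed bout times.  Switching is event-driven: bout
durations are sampled exactly and the integrator steps to each switching
instant (the final partial step is shortened), so the switching process
itself carries no discretization bias.

Time integration is a one-step implicit theta-scheme: Crank-Nicolson in the
interior of each bout for second-order accuracy, with two backward-Euler
startup steps immediately after every switch (Rannacher smoothing) to damp
the transient injected by the changed boundary condition.  All solves are
small dense linear systems; the two per-mode step matrices are factorized
(inverted) once per run.

The module also provides a deterministic solver for the closed-spiracle
relaxation transient (the intuition behind the flutter factor: shortly after
the spiracle closes, the concentration gradient at the tracheole - and hence
the uptake - has barely changed).  Being linear and deterministic, that
problem is integrated exactly in time through an eigendecomposition of the
discrete diffusion operator; only spatial discretization error remains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .model import (
    FlutterSchedule,
    TrachealModel,
    WaterModel,
    open_profile,
    open_uptake,
)
from .bvp import open_uptake_convective

__all__ = [
    "SimulationGrid",
    "EnsembleResult",
    "simulate_flutter",
    "simulate_water_flutter",
    "estimate_flutter_factor_mc",
    "closed_relaxation",
]

_N_BATCHES = 20  # batch-means blocks when n_realizations == 1
_RANNACHER_STEPS = 2  # backward-Euler steps after each switch


@dataclass(frozen=True)
class SimulationGrid:
    """Numerical settings for a Monte-Carlo run.

    ``dt``, ``t_burn`` and ``t_sample`` default (``None``) to values resolved
    from the physical timescales: dt = min(d_o, d_c)/20, t_burn =
    max(10/r, 5 L^2/D), t_sample = 10 t_burn.
    """

    n_x: int = 101
    dt: float | None = None
    t_burn: float | None = None
    t_sample: float | None = None
    n_realizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_x < 50:
            raise ValueError(f"n_x must be >= 50, got {self.n_x}")
        for name in ("dt", "t_burn", "t_sample"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.n_realizations < 1:
            raise ValueError(
                f"n_realizations must be >= 1, got {self.n_realizations}"
            )

    def resolved(
        self, schedule: FlutterSchedule, diffusion_time: float
    ) -> "SimulationGrid":
        """Fill in ``None`` fields from the physical timescales."""
        d_o, d_c = schedule.d_open, schedule.d_closed
        dt = self.dt
        if dt is None:
            shortest = min(d_o, d_c)
            dt = (
                0.02 * diffusion_time
                if not math.isfinite(shortest)
                else shortest / 20.0
            )
        t_burn = self.t_burn
        if t_burn is None:
            t_burn = max(10.0 / schedule.r, 5.0 * diffusion_time)
        t_sample = self.t_sample if self.t_sample is not None else 10.0 * t_burn
        shortest = min(d_o, d_c)
        if math.isfinite(shortest) and dt > shortest / 10.0:
            warnings.warn(
                f"dt = {dt:g} exceeds a tenth of the shortest mean bout "
                f"({shortest:g} s); switching may be under-resolved",
                stacklevel=2,
            )
        return replace(self, dt=dt, t_burn=t_burn, t_sample=t_sample)


@dataclass(frozen=True)
class EnsembleResult:
    """Stationary statistics of a Monte-Carlo ensemble.

    ``uptake_mean`` is the time/ensemble-averaged boundary flux times the
    tube cross-section: oxygen uptake at the tracheole for
    :func:`simulate_flutter`, water loss at the spiracle for
    :func:`simulate_water_flutter`.
    """

    x_grid: np.ndarray
    mean_profile: np.ndarray
    profile_se: np.ndarray
    uptake_mean: float
    uptake_se: float
    realized_p: float
    realized_p_se: float
    n_switches: int
    seed: int
    open_bouts: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    closed_bouts: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


class _ThetaStepper:
    """Pre-factorized theta-scheme steps for one boundary mode.

    Step: c_new = A^-1 (B c + b) with A = I - theta dt M, B = I + (1-theta)
    dt M on PDE rows; Dirichlet rows are identity rows with b carrying the
    boundary value.  M is the dense discrete operator, g the constant source.
    """

    def __init__(self, M, g, dirichlet, dt):
        self.M, self.g, self.dirichlet, self.dt = M, g, dirichlet, dt
        self.A_inv = {}
        self.B = {}
        self.b = {}
        for theta in (1.0, 0.5):
            A, B, b = _assemble_theta(M, g, dirichlet, dt, theta)
            self.A_inv[theta] = np.linalg.inv(A)
            self.B[theta] = B
            self.b[theta] = b

    def step(self, c, theta):
        return self.A_inv[theta] @ (self.B[theta] @ c + self.b[theta])

    def step_partial(self, c, dt, theta):
        A, B, b = _assemble_theta(self.M, self.g, self.dirichlet, dt, theta)
        return np.linalg.solve(A, B @ c + b)


def _assemble_theta(M, g, dirichlet, dt, theta):
    n = M.shape[0]
    A = np.eye(n) - theta * dt * M
    B = np.eye(n) + (1.0 - theta) * dt * M
    b = dt * g.copy()
    for row, value in dirichlet.items():
        A[row, :] = 0.0
        A[row, row] = 1.0
        B[row, :] = 0.0
        b[row] = value
    return A, B, b


def _oxygen_operators(model: TrachealModel, n_x: int):
    """Discrete operators (M, g, dirichlet) for the open and closed modes."""
    h = model.L / (n_x - 1)
    D, v = model.D, model.v
    if v != 0.0 and abs(v) * h / D >= 2.0:
        raise ValueError(
            f"cell Peclet number |v| h / D = {abs(v) * h / D:.3g} >= 2; "
            "increase n_x"
        )
    diff = D / h**2
    adv = v / (2.0 * h)
    M = np.zeros((n_x, n_x))
    for j in range(1, n_x - 1):
        M[j, j - 1] = diff + adv
        M[j, j] = -2.0 * diff
        M[j, j + 1] = diff - adv
    g = np.zeros(n_x)
    open_M = M.copy()
    open_dir = {0: 0.0, n_x - 1: model.A}
    closed_M = M.copy()
    # ghost node for -D c' + v c = 0 at x = L
    closed_M[n_x - 1, n_x - 2] = 2.0 * diff
    closed_M[n_x - 1, n_x - 1] = -2.0 * diff + 2.0 * v / h - v**2 / D
    closed_dir = {0: 0.0}
    return (open_M, g, open_dir), (closed_M, g, closed_dir)


def _water_operators(water: WaterModel, L: float, n_x: int):
    h = L / (n_x - 1)
    Dw, k = water.D_w, water.k
    diff = Dw / h**2
    M = np.zeros((n_x, n_x))
    M[0, 1] = 2.0 * diff
    M[0, 0] = -2.0 * diff - k
    for j in range(1, n_x - 1):
        M[j, j - 1] = diff
        M[j, j] = -2.0 * diff - k
        M[j, j + 1] = diff
    g = np.full(n_x, k * water.I)
    g[0] = k * water.I
    open_M = M.copy()
    open_dir = {n_x - 1: water.A_w}
    closed_M = M.copy()
    closed_M[n_x - 1, n_x - 2] = 2.0 * diff
    closed_M[n_x - 1, n_x - 1] = -2.0 * diff - k
    closed_dir = {}
    return (open_M, g, open_dir), (closed_M, g, closed_dir)


def _run_realization(
    steppers,
    c0,
    p,
    d_o,
    d_c,
    dt,
    t_burn,
    t_sample,
    rng,
    measure,
    bounds,
    collect_bouts,
):
    """Integrate one realization; return per-realization statistics.

    ``measure(c, mode)`` gives the instantaneous uptake/loss; ``bounds`` is
    an (lo, hi, tol) maximum-principle check or None.
    """
    c = c0.copy()
    t_total = t_burn + t_sample
    mode = 0 if rng.random() < p else 1  # 0 = open, 1 = closed
    t = 0.0
    n_switches = 0
    open_bouts: list[float] = []
    closed_bouts: list[float] = []

    acc_profile = np.zeros_like(c)
    batch_flux = np.zeros(_N_BATCHES)
    batch_time = np.zeros(_N_BATCHES)
    batch_profiles = np.zeros((_N_BATCHES, c.size))
    time_open = 0.0
    since_switch = 0  # steps since last mode switch (Rannacher control)

    if bounds is not None:
        lo, hi, tol = bounds

    def advance(step_dt, partial):
        nonlocal c, t, time_open, acc_profile
        theta = 1.0 if since_switch < _RANNACHER_STEPS else 0.5
        stepper = steppers[mode]
        if partial:
            c = stepper.step_partial(c, step_dt, theta)
        else:
            c = stepper.step(c, theta)
        if bounds is not None and (c.min() < lo - tol or c.max() > hi + tol):
            raise RuntimeError(
                f"maximum principle violated: profile left [{lo:g}, {hi:g}] "
                f"by more than {tol:g} at t = {t:g}"
            )
        t_new = t + step_dt
        if t_new > t_burn:
            w = min(step_dt, t_new - t_burn)  # time inside sampling window
            j = min(int((t_new - t_burn) / t_sample * _N_BATCHES), _N_BATCHES - 1)
            flux = measure(c, mode)
            batch_flux[j] += w * flux
            batch_time[j] += w
            batch_profiles[j] += w * c
            acc_profile += w * c
            if mode == 0:
                time_open += w
        t = t_new

    while t < t_total - 1e-12:
        mean_bout = d_o if mode == 0 else d_c
        bout = (
            rng.exponential(mean_bout)
            if math.isfinite(mean_bout)
            else t_total - t
        )
        t_end = min(t + bout, t_total)
        completed = t + bout <= t_total
        seg = t_end - t
        n_full = int(seg / dt)
        for i in range(n_full):
            advance(dt, partial=False)
            since_switch += 1
        rem = t_end - t
        if rem > 1e-12 * max(dt, 1.0):
            advance(rem, partial=True)
            since_switch += 1
        if completed and collect_bouts:
            (open_bouts if mode == 0 else closed_bouts).append(bout)
        if completed:
            n_switches += 1
            mode = 1 - mode
            since_switch = 0

    total_time = batch_time.sum()
    mean_profile = acc_profile / total_time
    uptake = batch_flux.sum() / total_time
    occupied = batch_time > 0
    batch_means = batch_flux[occupied] / batch_time[occupied]
    batch_prof_means = batch_profiles[occupied] / batch_time[occupied, None]
    return {
        "mean_profile": mean_profile,
        "uptake": uptake,
        "realized_p": time_open / total_time,
        "n_switches": n_switches,
        "open_bouts": open_bouts,
        "closed_bouts": closed_bouts,
        "batch_means": batch_means,
        "batch_profiles": batch_prof_means,
    }


def _ensemble(results, x, seed):
    uptakes = np.array([r["uptake"] for r in results])
    profiles = np.array([r["mean_profile"] for r in results])
    realized = np.array([r["realized_p"] for r in results])
    n = len(results)
    if n > 1:
        uptake_se = float(uptakes.std(ddof=1) / math.sqrt(n))
        profile_se = profiles.std(axis=0, ddof=1) / math.sqrt(n)
        realized_se = float(realized.std(ddof=1) / math.sqrt(n))
    else:
        bm = results[0]["batch_means"]
        bp = results[0]["batch_profiles"]
        nb = bm.size
        uptake_se = float(bm.std(ddof=1) / math.sqrt(nb))
        profile_se = bp.std(axis=0, ddof=1) / math.sqrt(nb)
        realized_se = float("nan")
    open_bouts = np.concatenate(
        [np.asarray(r["open_bouts"], dtype=float) for r in results]
    )
    closed_bouts = np.concatenate(
        [np.asarray(r["closed_bouts"], dtype=float) for r in results]
    )
    return EnsembleResult(
        x_grid=x,
        mean_profile=profiles.mean(axis=0),
        profile_se=profile_se,
        uptake_mean=float(uptakes.mean()),
        uptake_se=uptake_se,
        realized_p=float(realized.mean()),
        realized_p_se=realized_se,
        n_switches=int(sum(r["n_switches"] for r in results)),
        seed=seed,
        open_bouts=np.asarray(open_bouts, dtype=float),
        closed_bouts=np.asarray(closed_bouts, dtype=float),
    )


def simulate_flutter(
    model: TrachealModel,
    schedule: FlutterSchedule,
    grid: SimulationGrid | None = None,
) -> EnsembleResult:
    """Monte-Carlo estimate of the stationary flutter-phase oxygen statistics.

    Each realization starts from the always-open steady profile with the
    initial mode drawn Bernoulli(p) (near-stationary start), integrates
    through burn-in, then accumulates the time-averaged concentration profile
    and tracheole uptake ``pi a^2 D dc/dx(0)`` over the sampling window.
    Oxygen concentrations are checked against the maximum principle
    (0 <= c <= A) at every step.
    """
    grid = (grid or SimulationGrid()).resolved(schedule, model.diffusion_time)
    (open_op, closed_op) = _oxygen_operators(model, grid.n_x)
    steppers = (
        _ThetaStepper(*open_op, grid.dt),
        _ThetaStepper(*closed_op, grid.dt),
    )
    x = np.linspace(0.0, model.L, grid.n_x)
    c0 = np.asarray(open_profile(x, model))
    h = x[1] - x[0]
    area = model.cross_section

    def measure(c, mode):
        slope = (-3.0 * c[0] + 4.0 * c[1] - c[2]) / (2.0 * h)
        return area * (model.D * slope - model.v * c[0])

    bounds = (0.0, model.A, 1e-6 * max(model.A, 1.0)) if model.A >= 0 else None
    seeds = np.random.SeedSequence(grid.seed).spawn(grid.n_realizations)
    results = [
        _run_realization(
            steppers,
            c0,
            schedule.p,
            schedule.d_open,
            schedule.d_closed,
            grid.dt,
            grid.t_burn,
            grid.t_sample,
            np.random.default_rng(s),
            measure,
            bounds,
            collect_bouts=True,
        )
        for s in seeds
    ]
    return _ensemble(results, x, grid.seed)


def simulate_water_flutter(
    water: WaterModel,
    schedule: FlutterSchedule,
    L: float,
    a: float,
    grid: SimulationGrid | None = None,
) -> EnsembleResult:
    """Monte-Carlo estimate of the flutter-phase water loss.

    ``uptake_mean`` is W_flutter: the time average over the whole flutter
    cycle of the instantaneous outward diffusive flux at the spiracle
    (identically zero while closed).  Realizations start from the always-open
    steady cosh profile.
    """
    diffusion_time = L**2 / water.D_w
    grid = (grid or SimulationGrid()).resolved(schedule, diffusion_time)
    (open_op, closed_op) = _water_operators(water, L, grid.n_x)
    steppers = (
        _ThetaStepper(*open_op, grid.dt),
        _ThetaStepper(*closed_op, grid.dt),
    )
    x = np.linspace(0.0, L, grid.n_x)
    if water.k > 0:
        q = math.sqrt(water.k / water.D_w)
        c0 = water.I + (water.A_w - water.I) * np.cosh(q * x) / math.cosh(q * L)
    else:
        c0 = np.full_like(x, water.A_w)
    h = x[1] - x[0]
    area = math.pi * a**2

    def measure(c, mode):
        if mode != 0:
            return 0.0
        slope = (3.0 * c[-1] - 4.0 * c[-2] + c[-3]) / (2.0 * h)
        return -area * water.D_w * slope

    lo = min(water.A_w, water.I, float(c0.min()))
    hi = max(water.A_w, water.I, float(c0.max()))
    bounds = (lo, hi, 1e-6 * max(hi - lo, 1.0))
    seeds = np.random.SeedSequence(grid.seed).spawn(grid.n_realizations)
    results = [
        _run_realization(
            steppers,
            c0,
            schedule.p,
            schedule.d_open,
            schedule.d_closed,
            grid.dt,
            grid.t_burn,
            grid.t_sample,
            np.random.default_rng(s),
            measure,
            bounds,
            collect_bouts=True,
        )
        for s in seeds
    ]
    return _ensemble(results, x, grid.seed)


def estimate_flutter_factor_mc(
    model: TrachealModel,
    schedule: FlutterSchedule,
    grid: SimulationGrid | None = None,
) -> tuple[float, float]:
    """Monte-Carlo flutter factor f_hat = uptake_mean / U_open with its
    propagated standard error."""
    result = simulate_flutter(model, schedule, grid)
    u_open = open_uptake(model) if model.v == 0.0 else open_uptake_convective(model)
    return result.uptake_mean / u_open, result.uptake_se / u_open


def closed_relaxation(
    model: TrachealModel, t_list, n_x: int = 401
) -> np.ndarray:
    """Deterministic relaxation after the spiracle closes.

    Starting from the always-open steady profile A x / L, the spiracle closes
    at t = 0 (no-flux at x = L; absorbing tracheole at x = 0) and the oxygen
    drains into the tissues.  Returns the profile at each requested time,
    shape ``(len(t_list), n_x)``.  Shortly after closure the tracheole-end
    slope - hence the uptake - is nearly unchanged; at long times the profile
    decays to zero.

    Integration is exact in time (eigendecomposition of the discrete
    diffusion operator); only the O(h^2) spatial error remains.
    """
    t_arr = np.atleast_1d(np.asarray(t_list, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("relaxation times must be >= 0")
    if model.v != 0.0:
        raise ValueError("closed_relaxation models pure diffusion (v = 0)")
    x = np.linspace(0.0, model.L, n_x)
    h = x[1] - x[0]
    diff = model.D / h**2
    m = n_x - 1  # unknowns j = 1..n_x-1 (c(0) = 0 eliminated)
    # Operator: tridiag(diff, -2 diff, diff) with a doubled sub-diagonal
    # entry at the Neumann ghost row; the similarity transform
    # S = diag(1, ..., 1, 1/sqrt(2)) makes it symmetric, so the exact
    # propagator is an eigendecomposition away.
    main = np.full(m, -2.0 * diff)
    off = np.full(m - 1, diff)
    off[-1] = math.sqrt(2.0) * diff
    eigvals, Q = eigh_tridiagonal(main, off)
    scale = np.ones(m)
    scale[-1] = 1.0 / math.sqrt(2.0)
    c0 = model.A * x[1:] / model.L
    coeffs = Q.T @ (scale * c0)
    out = np.zeros((t_arr.size, n_x))
    for i, t in enumerate(t_arr):
        out[i, 1:] = (Q @ (np.exp(eigvals * t) * coeffs)) / scale
    return out
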