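"""Monte-Carlo switching simulator and the deterministic relaxation solver."""

import math

import numpy as np
import pytest
from scipy import stats

from spiraflux import (
    FlutterSchedule,
    SimulationGrid,
    TrachealModel,
    WaterModel,
    closed_relaxation,
    estimate_flutter_factor_mc,
    flutter_factor,
    open_uptake,
    simulate_flutter,
    simulate_water_flutter,
    water_open_loss,
)


def eigen_series(x, t, L, D, A, n_terms=50):
    """Separation-of-variables solution of the closed-spiracle relaxation:
    absorbing end at 0, no-flux end at L, initial profile A x / L."""
    n = np.arange(n_terms)
    lam = (n + 0.5) * np.pi / L
    b = 2.0 * A / L**2 * (-1.0) ** n / lam**2
    return (b[None, :] * np.sin(np.outer(x, lam)) * np.exp(-D * lam**2 * t)).sum(
        axis=1
    )


class TestSimulateFlutter:
    def test_always_open_recovers_steady_state(self, unit_tube):
        """p = 1 is deterministic: the linear profile and U_open exactly."""
        grid = SimulationGrid(n_x=51, t_burn=1.0, t_sample=5.0, n_realizations=2)
        schedule = FlutterSchedule(p=1.0, r=1.0)
        result = simulate_flutter(unit_tube, schedule, grid)
        np.testing.assert_allclose(
            result.mean_profile, result.x_grid / unit_tube.L, atol=1e-9
        )
        assert result.uptake_mean == pytest.approx(open_uptake(unit_tube), rel=1e-6)

    def test_zero_ambient_gives_zero(self):
        model = TrachealModel(L=0.5, A=0.0)
        grid = SimulationGrid(n_x=51, t_burn=0.5, t_sample=2.0, n_realizations=2)
        result = simulate_flutter(model, FlutterSchedule(p=0.3, r=5.0), grid)
        np.testing.assert_allclose(result.mean_profile, 0.0, atol=1e-14)
        assert result.uptake_mean == 0.0

    def test_estimate_within_three_se_of_closed_form(self, unit_tube):
        schedule = FlutterSchedule(p=0.5, r=5.0)
        grid = SimulationGrid(n_x=81, n_realizations=40, t_sample=80.0, seed=11)
        f_hat, se = estimate_flutter_factor_mc(unit_tube, schedule, grid)
        f = flutter_factor(0.5, schedule.switching_number(1.0, 0.176))
        assert abs(f_hat - f) < 3 * se
        assert se > 0

    def test_fast_flutter_boosts_uptake_far_above_p(self, unit_tube):
        """At r = 100/s a p = 0.09 schedule recovers ~70% of the always-open
        uptake (f(0.09, 568) = 0.702), an almost eight-fold gain."""
        schedule = FlutterSchedule(p=0.09, r=100.0)
        grid = SimulationGrid(n_x=81, n_realizations=10, t_sample=40.0, seed=7)
        f_hat, se = estimate_flutter_factor_mc(unit_tube, schedule, grid)
        f = flutter_factor(0.09, schedule.switching_number(1.0, 0.176))
        assert abs(f_hat - f) < 3 * se
        assert f_hat > 5 * schedule.p

    def test_silkworm_gain_reproduced(self, unit_tube, silkworm_schedule):
        """Silkworm fluttering raises uptake ~2.9-fold over p*U_open."""
        grid = SimulationGrid(n_x=81, n_realizations=60, t_sample=150.0, seed=23)
        f_hat, se = estimate_flutter_factor_mc(unit_tube, silkworm_schedule, grid)
        gain = f_hat / silkworm_schedule.p
        gain_se = se / silkworm_schedule.p
        assert abs(gain - 2.9) < 3 * gain_se + 0.05  # 2.9 is itself rounded

    def test_realized_p_matches_schedule(self, unit_tube):
        schedule = FlutterSchedule(p=0.3, r=5.0)
        grid = SimulationGrid(n_x=51, n_realizations=30, t_sample=60.0, seed=3)
        result = simulate_flutter(unit_tube, schedule, grid)
        assert abs(result.realized_p - 0.3) < 3 * result.realized_p_se

    def test_bout_durations_exponential(self):
        """KS test of sampled open bouts against Exp(d_o) at alpha = 0.01."""
        model = TrachealModel(L=0.3)
        schedule = FlutterSchedule(p=0.5, r=20.0)  # d_o = d_c = 0.1 s
        grid = SimulationGrid(
            n_x=50, t_burn=2.0, t_sample=300.0, n_realizations=4, seed=17
        )
        result = simulate_flutter(model, schedule, grid)
        assert result.n_switches >= 1e4
        ks = stats.kstest(result.open_bouts, "expon", args=(0, schedule.d_open))
        assert ks.pvalue > 0.01

    def test_ergodicity_time_vs_ensemble_average(self):
        """One long realization agrees with an ensemble of short ones."""
        model = TrachealModel(L=0.5)
        schedule = FlutterSchedule(p=0.5, r=5.0)
        long_grid = SimulationGrid(
            n_x=51, t_burn=8.0, t_sample=600.0, n_realizations=1, seed=29
        )
        ens_grid = SimulationGrid(
            n_x=51, t_burn=8.0, t_sample=30.0, n_realizations=25, seed=31
        )
        long_run = simulate_flutter(model, schedule, long_grid)
        ens_run = simulate_flutter(model, schedule, ens_grid)
        combined = math.hypot(long_run.uptake_se, ens_run.uptake_se)
        assert abs(long_run.uptake_mean - ens_run.uptake_mean) < 3 * combined

    def test_discretization_converged(self, unit_tube):
        """Halving dt and doubling n_x moves uptake by < 1 SE (same bout
        sequences via a shared seed, so the difference is pure bias)."""
        schedule = FlutterSchedule(p=0.2, r=2.0)
        coarse = SimulationGrid(
            n_x=101, dt=0.03125, n_realizations=25, t_sample=100.0, seed=41
        )
        fine = SimulationGrid(
            n_x=201, dt=0.015625, n_realizations=25, t_sample=100.0, seed=41
        )
        res_c = simulate_flutter(unit_tube, schedule, coarse)
        res_f = simulate_flutter(unit_tube, schedule, fine)
        assert abs(res_c.uptake_mean - res_f.uptake_mean) < res_c.uptake_se

    def test_same_seed_bitwise_reproducible(self, unit_tube):
        schedule = FlutterSchedule(p=0.4, r=4.0)
        grid = SimulationGrid(n_x=51, t_burn=2.0, t_sample=10.0, n_realizations=3, seed=5)
        r1 = simulate_flutter(unit_tube, schedule, grid)
        r2 = simulate_flutter(unit_tube, schedule, grid)
        assert r1.uptake_mean == r2.uptake_mean
        np.testing.assert_array_equal(r1.mean_profile, r2.mean_profile)

    def test_underresolved_dt_warns(self, unit_tube):
        schedule = FlutterSchedule(p=0.5, r=10.0)  # bouts 0.2 s
        grid = SimulationGrid(
            n_x=51, dt=0.1, t_burn=1.0, t_sample=3.0, n_realizations=1, seed=1
        )
        with pytest.warns(UserWarning, match="under-resolved"):
            simulate_flutter(unit_tube, schedule, grid)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SimulationGrid(n_x=10)
        with pytest.raises(ValueError):
            SimulationGrid(dt=-0.1)
        with pytest.raises(ValueError):
            SimulationGrid(n_realizations=0)


class TestSimulateWater:
    def test_always_open_matches_closed_form_loss(self, water_k1):
        """p = 1 starts at the cosh steady state; loss equals W_open."""
        grid = SimulationGrid(n_x=201, t_burn=1.0, t_sample=5.0, n_realizations=2)
        result = simulate_water_flutter(
            water_k1, FlutterSchedule(p=1.0, r=1.0), 1.0, 0.05, grid
        )
        expect = water_open_loss(water_k1, 1.0, 0.05)
        assert result.uptake_mean == pytest.approx(expect, rel=2e-4)

    def test_equilibrium_no_transfer_no_loss(self):
        """k = 0 with w = A_w everywhere stays at equilibrium: zero loss."""
        water = WaterModel(k=0.0, I=0.3, A_w=0.3)
        grid = SimulationGrid(n_x=51, t_burn=1.0, t_sample=5.0, n_realizations=2)
        result = simulate_water_flutter(
            water, FlutterSchedule(p=0.4, r=3.0), 1.0, 0.05, grid
        )
        assert abs(result.uptake_mean) < 1e-12


class TestClosedRelaxation:
    def test_initial_condition_exact(self, unit_tube):
        prof = closed_relaxation(unit_tube, [0.0], n_x=101)
        x = np.linspace(0, 1, 101)
        np.testing.assert_allclose(prof[0], x, atol=1e-14)

    def test_matches_eigenfunction_series(self, unit_tube):
        """Max-norm agreement < 1e-4 A with the 50-term series."""
        tau = unit_tube.diffusion_time
        times = [0.01 * tau, 0.1 * tau, 1.0 * tau]
        prof = closed_relaxation(unit_tube, times, n_x=401)
        x = np.linspace(0, 1, 401)
        for i, t in enumerate(times):
            series = eigen_series(x, t, unit_tube.L, unit_tube.D, unit_tube.A)
            assert np.max(np.abs(prof[i] - series)) < 1e-4 * unit_tube.A

    def test_mass_and_slope_decrease(self, unit_tube):
        tau = unit_tube.diffusion_time
        times = [0.05 * tau, 0.2 * tau, 0.8 * tau]
        prof = closed_relaxation(unit_tube, times, n_x=201)
        x = np.linspace(0, 1, 201)
        masses = [np.trapezoid(p, x) for p in prof]
        slopes = [(-3 * p[0] + 4 * p[1] - p[2]) / (2 * (x[1] - x[0])) for p in prof]
        assert all(b < a for a, b in zip(masses, masses[1:]))
        assert all(b < a for a, b in zip(slopes, slopes[1:]))

    def test_long_time_decays_to_zero(self, unit_tube):
        prof = closed_relaxation(unit_tube, [20 * unit_tube.diffusion_time], n_x=101)
        assert np.max(np.abs(prof[0])) < 1e-3

    def test_mass_balance_with_absorbed_flux(self, unit_tube):
        """d(mass)/dt equals minus the flux absorbed at the tracheole."""
        t0, dt = 0.1 * unit_tube.diffusion_time, 1e-3
        prof = closed_relaxation(unit_tube, [t0 - dt, t0, t0 + dt], n_x=401)
        x = np.linspace(0, 1, 401)
        h = x[1] - x[0]
        dmass_dt = (np.trapezoid(prof[2], x) - np.trapezoid(prof[0], x)) / (2 * dt)
        slope0 = (-3 * prof[1][0] + 4 * prof[1][1] - prof[1][2]) / (2 * h)
        flux_absorbed = unit_tube.D * slope0
        assert dmass_dt == pytest.approx(-flux_absorbed, rel=1e-3)

    def test_domain_errors(self, unit_tube):
        with pytest.raises(ValueError):
            closed_relaxation(unit_tube, [-1.0])
        with pytest.raises(ValueError):
            closed_relaxation(TrachealModel(L=1.0, v=-0.1), [0.1])
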