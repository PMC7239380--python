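# Methods

## Model and assumptions

The tracheal network is reduced to a single one-dimensional interval of
length *L*: branches are assumed to conserve total cross-sectional area, so
branching does not affect the flux reaching the tracheoles, and the many
terminal tracheoles are represented by one perfectly absorbing endpoint at
*x* = 0 (*c* = 0). The spiracle at *x* = *L* imposes the ambient
concentration *A* while open and zero flux while closed. Open and closed
bout durations during flutter are independent exponentials with means
*d*_o = 1/((1 − *p*)*r*) and *d*_c = 1/(*p r*); the concentration is then a
piecewise-deterministic Markov process. Oxygen transport is pure diffusion
by default; an advection term −*v c*_x (with *v* < 0 for the inward flow
caused by sub-ambient tracheal pressure) is supported, in which case the
closed-spiracle condition becomes the convective no-flux condition
−*D c*_x(*L*) + *v c*(*L*) = 0 and the always-open uptake is
π*a*²*A v*/(e^{*vL*/*D*} − 1). (The latter form is chosen so the uptake is
positive for either sign of *v* and has the correct diffusive limit
π*a*²*DA*/*L* as *v* → 0, evaluated by series for |*vL*/*D*| < 10⁻⁶.)

Water vapour *w*(*x*, *t*) obeys *w*_t = *D*_w *w*_xx + *k*(*I* − *w*) with
a reflecting tracheole end (*w*_x(0) = 0): the trachea gains water through
its walls at rate *k* toward the closed-spiracle equilibrium level *I*, and
loses it through the open spiracle (*w*(*L*) = *A*_w while open, no flux
while closed). Not modelled: CO₂ dynamics, finite spiracle radius, partial
tracheole uptake, pressure-driven tube volume changes, network topology,
and the energetic cost of fluttering.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| *L* | tracheal length | cm | — (case-specific, 0.28–1.6 in the case table) |
| *a* | tube radius | cm | 0.05; cancels in *f*, *G*, *f*_w |
| *D* | oxygen diffusivity | cm²/s | 0.176 |
| *D*_w | water-vapour diffusivity | cm²/s | 0.282 |
| *A*, *A*_w, *I* | ambient O₂ / ambient vapour / interior vapour level | arbitrary | 1, 0, 1 (only ratios and differences matter) |
| *p* | open fraction during flutter | — | case-specific; *p* = 1 allowed (always open), *p* = 0 rejected |
| *r* | flutter rate | 1/s | case-specific |
| *v* | convection velocity | cm/s | 0 |
| *k* | wall water transfer rate | 1/s | — (the one genuinely unknown parameter) |

All quantities are CGS + seconds. The dimensionless groups are
*s* = *rL*²/*D*, σ = *rL*²/*D*_w, κ = *kL*²/*D*_w, *V* = *vL*/*D*.
tanh(√s)/√s is evaluated by its series (1 − *s*/3) for *s* < 10⁻¹² to avoid
the removable 0/0.

## Two-mode expectation BVPs

Splitting the stationary expectation by spiracle state,
u₀ = lim E[*c*·1{open}] and u₁ = lim E[*c*·1{closed}], yields a coupled
linear system: each component carries the PDE operator, its own boundary
condition at *x* = *L* (u₀(*L*) = *p A*; convective no-flux for u₁), and
exchange terms ±((1 − *p*)*r* u₀ − *p r* u₁) at the mode-switching rates.
For water, the wall source *k*(*I* − *w*) splits as *k*(*p I* − w₀) and
*k*((1 − *p*)*I* − w₁), the interior level being weighted by the stationary
mode probability. The flutter factor is the tracheole flux of u₀ + u₁ over
the always-open uptake; the water factor is the open-component spiracle
flux −*D*_w w₀′(*L*) over the always-open loss
(*I* − *A*_w)√(*k D*_w)·tanh(√κ) — flux leaves only while the spiracle is
open, and the closed component carries none at *L* by construction.

These solvers are the normative implementation for the convective flutter
factor and for *f*_w; the corresponding printed closed forms are not
reimplemented (their typography is unreliable in the available source
material), and every BVP result is instead validated against the clean
closed form at *v* = 0 and against the Monte-Carlo simulator.

Discretization: second-order central differences on a uniform grid
(default 400 intervals), Neumann/Robin conditions via ghost nodes (second
order), boundary fluxes by one-sided three-point differences, direct sparse
solve with a residual check (< 10⁻⁸ max norm). A cell-Péclet guard refines
the grid automatically so |*v*|*h*/*D* < 2, keeping the central convection
stencil monotone. Observed convergence is second order (error vs the
analytic *f* drops ~16× from *n* = 100 to 400); at *n* = 400 the
closed-form agreement is ≲ 2×10⁻⁵ over *p* ∈ [0.02, 0.5], *s* ∈ [0.1, 100].
Large *s* or κ (≳ 10³ at the default grid) produce boundary layers of width
√(*D*/*r*) that need proportionally finer grids.

## Monte-Carlo simulator

Bout durations are sampled exactly from their exponential laws and the
integrator steps to each switching instant (event-driven switching; the
final partial step is shortened), so the switching process itself is
unbiased. Within bouts the PDE is advanced by a one-step implicit
θ-scheme: Crank–Nicolson (θ = ½) for second-order accuracy, with two
backward-Euler startup steps after every switch (Rannacher smoothing) to
damp the transient injected by the changed boundary condition and keep the
solution inside its maximum-principle bounds, which are asserted at every
step (tolerance 10⁻⁶·*A*). The two per-mode step matrices are built once
per run and applied as precomputed dense inverses; partial steps solve a
fresh system. Defaults: Δ*t* = min(*d*_o, *d*_c)/20 (warning above
bout/10), burn-in *t*_burn = max(10/*r*, 5*L*²/*D*) to cover both the
switching and diffusive relaxation timescales, sampling window
10·*t*_burn, 101 grid points. Each realization starts from the always-open
steady profile with its initial mode drawn Bernoulli(*p*) — near
stationarity, shortening burn-in.

Every run derives per-realization seeds from one parent `SeedSequence`, so
results are bit-reproducible for a given seed. Standard errors come from
the spread of per-realization time averages (with 20-block batch means
inside the window when only one realization is run); uptake estimates are
time averages of the instantaneous boundary flux (tracheole flux for
oxygen; outward spiracle flux, zero while closed, for water).

The deterministic closed-spiracle relaxation (linear profile initial
condition, absorbing/no-flux ends) is integrated exactly in time by
eigendecomposition of the symmetrized discrete diffusion operator, leaving
only the O(*h*²) spatial error; at 401 grid points it agrees with the
50-term eigenfunction series (λ_n = (n + ½)π/L) to < 10⁻⁵·*A* across
[0.01, 1]·*L*²/*D*.

## Validation strategy and problem sizes

Every quantity is computed by at least two independent routes:

- closed form vs BVP: |Δ*f*| < 10⁻⁴ over the full grid
  {0.02, 0.2, 0.5} × {0.1, 1, 10, 100} at 400 intervals;
- closed form vs Monte Carlo: within 3 standard errors on the reference
  configuration (*p* = 0.2, *r* = 2/s, *L* = 1 cm, 200 realizations,
  default windows), including the pointwise linearity of the stationary
  mean profile; representative corners of the (p, s) grid are spot-checked
  with smaller ensembles (10–40 realizations, windows of 40–150 s) whose
  3·SE tolerances scale accordingly;
- water BVP vs Monte Carlo (silkworm schedule, *k* = 1/s, 120
  realizations, 90 s windows) and vs the always-open closed form;
- closed forms vs independent `scipy.integrate.solve_bvp` collocation
  solves of the steady states.

The ensemble sizes and windows above are the package's test defaults,
chosen so the whole suite completes in a few minutes; all tolerances are
statistical (3·SE) or discretization-level, never tuned to a particular
draw.

## What the simulator does and does not emulate

The Monte-Carlo generator realizes exactly the model's idealizations:
memoryless bouts, a rigid one-dimensional tube, constant ambient
conditions, perfectly absorbing tracheoles. Agreement between simulator,
BVP, and closed form therefore validates the mathematics and the numerics,
not the biology: real bout distributions are not exactly exponential (the
stationary factors are insensitive to this, but the tests do not show it),
real tracheae exchange gas along their walls, and measured *p* is often an
assumption (the case table's `source_note` column marks these).

## Design choices and degenerate inputs

- *p* = 1 degenerates to the always-open problem everywhere; *p* = 0 is
  rejected (*f* and *G* are undefined).
- *f*_w at *k* = 0 (or *I* = *A*_w) is 0/0 since *W*_open vanishes; an
  error is raised rather than a limit guessed.
- The case table reproduces conventionally printed gains by half-up
  rounding at a per-case precision column; unrounded values are always
  reported alongside. The *Gromphadorhina* entry deliberately stores the
  printed truncations *p* = 0.28, *r* = 2.33 rather than the exact 2/7 and
  7/3 derived from its bouts, because the reported gain follows from the
  truncated inputs.
- Figure routines run headless (Agg); axis ranges default to
  *r* ∈ [10⁻², 10²]/s, *L* ∈ [0.05, 2] cm, *k* ∈ [10⁻³, 10²]/s, spanning
  all case-study values; the two relaxation snapshot times default to 0.05
  and 0.5 of *L*²/*D* and are parameters, not claims.

## Known limitations

- The flutter-rate → ∞ and κ → ∞ limits are approached numerically only as
  far as the grid resolves the associated boundary layers; tests therefore
  assert monotone approach plus a finite-distance bound rather than the
  literal limit.
- The simulator's cost scales with (bouts per window)·(grid points)², so
  very fast flutter with long windows is expensive; the estimator is
  unbiased at any window length, and standard errors quantify the cost of
  shortening them.
- Whole-cycle uptake treats the closed phase as contributing exactly zero
  and takes the phase fractions as given; CO₂-driven phase dynamics are out
  of scope.
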