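"""Monte-Carlo validation of the flutter factor.

Simulates the diffusion equation with a stochastically switching spiracle
boundary (exponential open/closed bouts) and compares the time/ensemble-
averaged uptake against the closed-form flutter factor.
"""

from spiraflux import (
    FlutterSchedule,
    SimulationGrid,
    TrachealModel,
    estimate_flutter_factor_mc,
    flutter_factor,
)

model = TrachealModel(L=1.0)  # 1 cm tube, D = 0.176 cm^2/s, A = 1
schedule = FlutterSchedule(p=0.2, r=2.0)
grid = SimulationGrid(n_x=81, n_realizations=30, t_sample=100.0, seed=42)

f_hat, se = estimate_flutter_factor_mc(model, schedule, grid)
f = flutter_factor(schedule.p, schedule.switching_number(model.L, model.D))

print(f"closed form   f = {f:.4f}")
print(f"Monte Carlo   f_hat = {f_hat:.4f} +/- {se:.4f}")
print(f"discrepancy   {abs(f_hat - f) / se:.2f} standard errors")
print()
print("The simulator integrates every realization between exactly sampled")
print("switching times; the estimate should sit within ~3 SE of the formula.")
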