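"""Water loss while fluttering: the water flutter factor.

Water enters the trachea through its walls at rate k and escapes through the
open spiracle.  f_w = W_flutter/W_open measures the fraction of the
always-open loss that fluttering retains.  For large k (when water loss
actually threatens the insect) f_w collapses to p — loss is set by the open
fraction, almost independent of the flutter rate — so a small p with a large
r conserves water without sacrificing oxygen.
"""

import numpy as np

from spiraflux import FlutterSchedule, WaterModel, water_flutter_factor_bvp

schedule = FlutterSchedule.from_durations(0.5, 5.0)  # silkworm, p = 0.091
L = 1.0

print(f"p = {schedule.p:.4f}  (dashed asymptote)")
print(f"{'k (1/s)':>10}  {'kappa':>8}  {'f_w':>8}")
for k in np.logspace(-2, 2.5, 7):
    water = WaterModel(k=k)  # D_w = 0.282 cm^2/s, unit vapour gradient
    fw = water_flutter_factor_bvp(water, schedule, L)
    print(f"{k:10.3g}  {water.kappa(L):8.3g}  {fw:8.4f}")
print()
print("f_w falls from ~1 (slow transfer: the tube refills slowly, so")
print("closing barely matters) to p (fast transfer: loss happens whenever")
print("the spiracle is open).")
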