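"""Flutter factor and respiratory gain for the giant Saturniid silkworm.

Open bouts of ~0.5 s separated by ~5 s closed bouts give an open fraction of
only 9%, yet with a 1 cm trachea the silkworm recovers 26% of the always-open
oxygen uptake — a 2.9-fold gain over what slow switching would deliver.
"""

from spiraflux import durations_to_rates, flutter_factor, respiratory_gain

d_open, d_closed = 0.5, 5.0  # s
L, D = 1.0, 0.176  # cm, cm^2/s

p, r = durations_to_rates(d_open, d_closed)
s = r * L**2 / D
f = flutter_factor(p, s)
G = respiratory_gain(p, s)

print(f"open fraction        p = {p:.4f}")
print(f"flutter rate         r = {r:.3f} /s")
print(f"dimensionless rate   s = rL^2/D = {s:.3f}")
print(f"flutter factor       f = {f:.4f}")
print(f"respiratory gain     G = f/p = {G:.3f}  (prints as 2.9)")
print()
print("f is the fraction of the always-open uptake retained while")
print("fluttering; G is the fold increase over the slow-switching uptake")
print("p*U_open. Spiracles shut 91% of the time still deliver 26% of the")
print("always-open oxygen supply.")
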