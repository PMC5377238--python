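"""Assay validation: calibration linearity and replicate variability.

Simulates NaHCO3 calibration-standard wells across concentrations, fits the
standard line to verify the A340 response is linear in CO2, then computes
replicate CVs at 0 %, 50 % and 80 % activity levels — the statistics used
to judge whether a plate assay is tight enough for screening.
"""

import dataclasses

import numpy as np

from samdcscreen.assay_kinetics import delta_au, linearity_check, validation_stats
from samdcscreen.synthetic_data import AssaySimConfig, simulate_standard

cfg = AssaySimConfig(noise_sd=0.002)
# the working NADH pool (~106 uM) bounds the linear detection range
concs = [0.0, 20.0, 40.0, 60.0, 80.0, 100.0]
pairs = []
for i, c in enumerate(concs):
    std = simulate_standard(c, dataclasses.replace(cfg, seed=100 + i))
    pairs.append((c, delta_au(std, 0, 5)))
slope, intercept, r2 = linearity_check(pairs)
print(f"standard line: dAU = {slope:.5f} * [CO2 uM] + {intercept:.4f},  R^2 = {r2:.4f}")
print(f"(simulator epsilon*l = {cfg.epsilon_l}; linear response confirms calibration)")
print()

# replicate dAU at three activity levels, 5% pipetting-style noise;
# 0% activity still shows the drift-only background signal
rng = np.random.default_rng(0)
enzyme_signal = 0.0637  # AU over 5 min at full activity
drift_signal = 0.0087  # AU over 5 min from exogenous CO2
levels = {0.0: 0.0, 50.0: 0.5, 80.0: 0.8}  # % activity -> fraction of signal
replicates = {
    lvl: [
        (drift_signal + enzyme_signal * f) * (1 + rng.normal(0, 0.05))
        for _ in range(3)
    ]
    for lvl, f in levels.items()
}
vs = validation_stats(replicates)
for lvl, st in sorted(vs.levels.items()):
    print(f"{lvl:5.0f}% activity: mean dAU = {st.mean:.4f}, CV = {st.cv_pct:5.2f}%, SEM = {st.sem:.4f}")
print()
print("CVs of a few percent across activity levels indicate the coupled assay")
print("is reproducible enough for single-concentration inhibitor screening.")
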