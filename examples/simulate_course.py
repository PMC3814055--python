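"""Simulate tumor regression under a conventional 2 Gy x 25 course.

Builds the default fractionation schedule (5 fractions/week with weekend
gaps), simulates the two-compartment volume trajectory for a corrected
survival law (A = 0.6, B = -1.5), and prints weekly volumes alongside the
conventional-model prediction (A = 1, B = 0).
"""

import numpy as np

from tumorlq import (
    KineticParams,
    RadiosensitivityParams,
    expand_regimen,
    simulate_course,
)

schedule = expand_regimen(n_fractions=25, dose_gy=2.0, fractions_per_week=5)
kinetics = KineticParams(t_pot=5.5, t_half=40.0)  # lung-like values, days
corrected = RadiosensitivityParams(0.35, 0.035, corr_a=0.6, corr_b=-1.5)
conventional = RadiosensitivityParams(0.35, 0.035, corr_a=1.0, corr_b=0.0)

v0 = 100.0  # baseline volume, cm^3
weeks = np.arange(0.0, 63.0, 7.0)
vol_corr = simulate_course(v0, schedule, corrected, kinetics, weeks)
vol_conv = simulate_course(v0, schedule, conventional, kinetics, weeks)

print(f"{'day':>4}  {'V corrected (cm^3)':>19}  {'V conventional (cm^3)':>22}")
for t, vc, vv in zip(weeks, vol_corr.volumes, vol_conv.volumes):
    print(f"{t:4.0f}  {vc:19.2f}  {vv:22.2f}")
print()
print(
    "The corrected model (per-fraction survival exp(-A*(aD+bD^2)+B)) kills\n"
    "more per fraction here (B = -1.5), so regression is faster throughout.\n"
    "Both curves keep shrinking past the end of the course (day 32): with\n"
    "T_half = 40 days, clearance of the lethally damaged pool dominates the\n"
    "volume long after the last fraction, and regrowth of the small\n"
    "surviving viable pool only takes over much later."
)
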