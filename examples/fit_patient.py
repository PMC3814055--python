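"""Fit the correction factors (A, B) to a noisy synthetic patient.

Generates one synthetic patient from an identifiable recovery design
(escalating doses, dense sampling), adds 5% multiplicative measurement
noise, fits (A, B) by bounded least squares, and compares the fit against
the zero-parameter conventional model.
"""

from tumorlq import KineticParams, compare_models
from tumorlq.synthetic import SyntheticPatientSpec, generate_trajectory, recovery_design

schedule, sample_times = recovery_design()
spec = SyntheticPatientSpec(
    v0=100.0, t_half=35.0, t_pot=5.5,
    true_corr_a=0.6, true_corr_b=-1.5,
    schedule=schedule, sample_times=sample_times,
    noise_cv=0.05, seed=42,
)
_, noisy = generate_trajectory(spec)

kinetics = KineticParams(t_pot=spec.t_pot, t_half=spec.t_half)
cmp = compare_models(noisy, schedule, spec.alpha, spec.beta, kinetics)
fit = cmp.fit_new

n2 = spec.alpha * 2.0 + spec.beta * 4.0  # lethal events at a 2 Gy fraction
print(f"true   A = {spec.true_corr_a:.3f}   B = {spec.true_corr_b:.3f}")
print(f"fitted A = {fit.corr_a_hat:.3f}   B = {fit.corr_b_hat:.3f}")
print(f"log survival per 2 Gy, -A*N+B:  true = "
      f"{-spec.true_corr_a * n2 + spec.true_corr_b:.3f}   fitted = "
      f"{-fit.corr_a_hat * n2 + fit.corr_b_hat:.3f}")
print(f"R^2  (corrected model)    = {fit.r_squared:.4f}")
print(f"R0^2 (conventional model) = {cmp.r0_squared:.4f}")
print()
print(
    "R^2 >= R0^2 always holds because the corrected model nests the\n"
    "conventional one (A = 1, B = 0 is inside the fit bounds).  Even on an\n"
    "identifiable design, 5% volume noise leaves (A, B) individually poorly\n"
    "determined (here the fitted A collapsed to its lower bound), while the\n"
    "combination -A*N+B -- the per-fraction log survival that actually\n"
    "drives the trajectory -- is recovered within a few percent."
)
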