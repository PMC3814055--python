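"""A nine-patient synthetic cohort study, shaped like the published one.

Draws four lung and five cervix synthetic patients (V0 and T_half uniform
over the published cohort ranges, T_pot fixed per cohort), fits (A, B) to
each noisy trajectory, scores the conventional comparator, and prints the
per-patient table plus cohort means.
"""

import numpy as np

from tumorlq import compare_models, generate_cohort, summarize_cohort

patients = generate_cohort(4, "lung", seed=2026, noise_cv=0.05)
patients += generate_cohort(5, "cervix", seed=2027, noise_cv=0.05)

rows = []
for i, p in enumerate(patients, start=1):
    cmp = compare_models(
        p.noisy, p.spec.schedule, p.spec.alpha, p.spec.beta, p.spec.kinetics
    )
    rows.append((i, p.spec.v0, p.spec.t_half, cmp.fit_new.corr_a_hat,
                 cmp.fit_new.corr_b_hat, cmp.fit_new.r_squared, cmp.r0_squared))

print(f"{'pt':>2} {'V0':>7} {'T_half':>7} {'A_hat':>7} {'B_hat':>7} "
      f"{'R^2':>7} {'R0^2':>7}")
for i, v0, th, a, b, r2, r0 in rows:
    print(f"{i:2d} {v0:7.1f} {th:7.1f} {a:7.3f} {b:7.3f} {r2:7.3f} {r0:7.3f}")

r2s = [r[5] for r in rows]
r0s = [r[6] for r in rows]
print()
print(f"cohort mean R^2  = {summarize_cohort(r2s):.3f}")
print(f"cohort mean R0^2 = {summarize_cohort(r0s):.3f}")
print(f"R^2 >= R0^2 in {sum(a >= b for a, b in zip(r2s, r0s))}/9 patients "
      "(guaranteed: the corrected model nests the conventional one)")
print()
print(
    "Under the uniform 2 Gy course the fitted (A, B) lie on the\n"
    "unidentifiable ridge -A*N(2Gy)+B = const, so individual factors are\n"
    "not comparable to the generating truth -- only the fit quality and\n"
    "the nesting ordering are meaningful here."
)
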