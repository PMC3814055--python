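# tumorlq

Quantitative modelling of tumor volume changes during fractionated
radiotherapy, for radiation oncology physicists and modellers who want to
turn sparse mid-treatment CT volume measurements into a treatment-response
estimate.

## The model

Cell kill per fraction follows a corrected linear-quadratic (LQ) survival
law.  Conventionally, the surviving fraction after a dose *D* is
S₀ = exp(−(αD + βD²)); here two dimensionless correction factors enter the
exponent:

    S = exp(−A·(αD + βD²) + B)

*A* rescales the double-strand-break term (capturing hypoxia, potentially
lethal damage repair, and the post-irradiation microenvironment) and *B*
adds kill not represented by α/β events (e.g. single-strand breaks leading
to reproductive death).  A = 1, B = 0 recovers the conventional model.

The tumor is two well-mixed compartments: viable cells N_l and lethally
damaged cells N_d.  Each fraction moves (1−S)·N_l into the damaged pool
(total count conserved at the instant of irradiation); between fractions

    N_l(t+Δt) = N_l(t)·exp(λΔt),   λ = ln2 / T_pot
    N_d(t+Δt) = N_d(t)·exp(−μΔt),  μ = ln2 / T_half

with T_pot the potential doubling time and T_half the clearance halving
time of damaged cells (days).  Volume is proportional to the total count:
V(t) = V₀·(N_l + N_d) with the state normalized to total 1 at baseline.

Given a measured volume series and the treatment schedule, `tumorlq` fits
(A, B) by bounded least squares (deterministic grid + Nelder–Mead
refinement), scores the fit with R² = 1 − SS_res/SS_tot, and compares it
against the zero-parameter conventional forward model (score R₀²).  Because
the corrected model nests the conventional one, R² ≥ R₀² always holds when
(1, 0) is inside the fit bounds.

A synthetic-data module generates cohorts with known ground-truth (A, B) —
initial volumes and halving times spanning the published nine-patient
validation cohort (four lung, five cervical tumors), lognormal
multiplicative measurement noise with median 1 — so estimation quality can
be measured against truth.

**A caveat worth knowing:** under a uniform-dose course every fraction
shares one survival value, so (A, B) are structurally unidentifiable along
the ridge −A·(αD+βD²) + B = const (and A is in any case only meaningful
relative to the assumed α, β).  Recovery of both factors requires dose
variation early in the schedule; `tumorlq.synthetic.recovery_design()`
provides such a study design.  See `docs/methods.md`.

## Worked example

`examples/fit_patient.py` generates one synthetic patient on the
identifiable recovery design (escalating 1–5 Gy fractions, dense sampling),
adds 5% measurement noise, and fits the correction factors:

```
true   A = 0.600   B = -1.500
fitted A = 0.010   B = -1.962
log survival per 2 Gy, -A*N+B:  true = -2.004   fitted = -1.970
R^2  (corrected model)    = 0.8424
R0^2 (conventional model) = -14.8592
```

The fitted trajectory explains the data well (R² = 0.84) and beats the
conventional comparator by a wide margin (R₀² is negative: worse than
predicting the mean volume).  Note what the noise does to the parameters:
A individually collapsed to its bound, while the combination −A·N + B —
the per-fraction log survival that actually drives the trajectory — is
recovered within a few percent.  On noiseless data the same fit returns
(0.600, −1.500) to ~1e−10.

Other examples: `examples/simulate_course.py` (weekly volumes under a
2 Gy × 25 course, corrected vs conventional) and `examples/cohort_study.py`
(a nine-patient synthetic cohort table with per-patient Â, B̂, R², R₀²).

## Command line

```bash
tumorlq synth    --cohort lung --n 9 --seed 1 --outdir cohort/
tumorlq fit      --volumes v.csv --schedule s.csv --config cfg.yaml --out fit.json
tumorlq compare  --volumes v.csv --schedule s.csv --config cfg.yaml --out cmp.json
tumorlq simulate --schedule s.csv --params p.yaml --out traj.csv
```

CSV dialects: volume series `time_days,volume_cm3`; schedules
`time_days,dose_gy`.  Every output embeds the package version and the full
effective configuration for provenance.

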