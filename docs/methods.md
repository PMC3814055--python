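# Methods

## Model

The package couples a corrected linear-quadratic (LQ) survival law to a
two-compartment cell-population recursion.

**Survival.** The mean lethal-event count per cell at dose D is
N(D) = αD + βD², and the corrected surviving fraction is

    S(D) = exp(−A·N(D) + B).

A > 0 is a multiplicative correction on the double-strand-break term and B
an additive offset for kill outside the α/β bookkeeping.  A = 1, B = 0 is
the conventional LQ model, which the corrected law therefore nests exactly.
S is computed as written: it is not clamped at 1.  When B > 0 (or B ≥ 0 at
zero dose) S can exceed 1; that is an ill-posed parameter combination, not
a numerical accident, so the survival routine emits a warning and the
fitting layer controls it through its box bounds.  Silently clamping would
hide the ill-posedness from the optimizer.

**Population dynamics.** Two well-mixed pools: viable cells N_l and
lethally damaged cells N_d, normalized so N_l + N_d = 1 at baseline (the
whole population viable).  A fraction at time t_k applies

    N_l ← S·N_l,    N_d ← N_d + (1−S)·N_l,

conserving the total exactly at the instant of irradiation.  Between
events the pools evolve exponentially with λ = ln2/T_pot (proliferation)
and μ = ln2/T_half (clearance of damaged cells).  Volume is proportional
to total count; the per-cell volume constant and absolute cell number are
unobservable from volume data, so the baseline measured volume V₀ carries
the scale: V(t) = V₀·(N_l(t) + N_d(t)).

Conventions, chosen once and used everywhere:

- All times in days; t = 0 is the first volume measurement, and fraction
  times live on the same axis.
- Evaluation at arbitrary times uses the same exponential laws over the
  partial interval since the last event (the unique continuous-time
  extension of the inter-fraction step).
- When an evaluation time coincides with a fraction time, the fraction is
  applied first ("post-fraction" reporting).  The total count — hence the
  volume — is continuous across the instant anyway; the convention matters
  only for the viable/damaged split.
- After the last fraction, viable regrowth at rate λ continues
  indefinitely; no plateau is imposed.
- Resuming: `simulate_course`/`state_at` accept an initial state at
  t_start.  A supplied state is treated as post-fraction, so a fraction
  exactly at t_start is not re-applied; on a fresh start a fraction at
  t = 0 is applied to the all-viable state.

**Closed-form check.** For k fractions of equal dose at spacing Δt,
starting all-viable at the first fraction and evaluated immediately after
fraction k, the recursion has the closed form

    N_l = S^k · e^{λ(k−1)Δt}
    N_d = (1−S) · e^{−μ(k−1)Δt} · (r^k − 1)/(r − 1),   r = S·e^{(λ+μ)Δt},

because the cells killed at fraction j are (1−S)·S^{j−1}·e^{λ(j−1)Δt}
(the viable pool grows between kills) and then decay for (k−j) intervals.
The test suite checks the recursion against this independently derived
expression for k = 1..30 (agreement ~1e−15 relative).

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| α | linear LQ sensitivity | Gy⁻¹ | 0.35 | standard literature tumor value |
| β | quadratic LQ sensitivity | Gy⁻² | 0.035 | α/β = 10 Gy, generic tumor |
| A | multiplicative correction | — | fitted (bounds 0.01–3) | brackets all published fits (0.17–0.85) with margin |
| B | additive correction | — | fitted (bounds −5–1) | brackets published fits (−2.95…−0.41); B ≤ 0 physical, small B > 0 allowed so the bound is not active at the conventional point |
| T_pot | potential doubling time | d | 5.5 (lung), 4.5 (cervix) | published cohort values |
| T_half | damaged-cell clearance halving time | d | per patient (cohort ranges 33.3–50.2 lung, 13.9–90.6 cervix) | published per-patient values; treated as a fixed input, never co-fitted |

Because A multiplies N(D), a fitted A is only interpretable relative to the
assumed (α, β): scaling α, β by c and A by 1/c changes nothing.  The
defaults are therefore required, documented configuration, not estimates.

## Fitting

The objective is the sum of squared volume residuals between the forward
simulation and the measurements; V₀ is the first measurement and its time
the origin.  Default residuals are in absolute volume (cm³) — the most
literal reading of "least squares" on volume data; a `residual_space=
"relative"` switch divides each residual by the measured volume at that
timepoint (equal fractional weighting), documenting the ambiguity of the
residual scale.  (Normalizing both sides by the fixed V₀ would merely
rescale the objective without moving the optimum, so that reading is not
offered as a switch.)

The optimizer is a deterministic two-stage search over the bound box: a
coarse grid (default 21×21) followed by bounded Nelder–Mead refinement
from the best cells (default 5 starts; xatol 1e−10, fatol 1e−16).  A
2-parameter problem does not need anything cleverer, and determinism
(bit-identical results for identical inputs) is worth more than speed
here.  The conventional point (1, 0) is always added to the start list
when inside the bounds, which makes the nesting inequality R² ≥ R₀² hold
by construction, not just asymptotically.  Non-convergence of every start
is flagged on the result (`converged=False`), never raised.

R² = 1 − SS_res/SS_tot with SS_tot about the mean of the measured values;
it is ≤ 1, can be negative, and is undefined (raised as an error) on a
constant measured series.  The conventional comparator R₀² simulates with
S₀ = exp(−N) and no free parameters.  Cohort summaries are plain
arithmetic means; a `drop_negative` switch exposes the alternative
convention of averaging only non-negative scores, since published cohort
summaries of the comparator appear to follow it.

## Identifiability

This is the model's central statistical subtlety.  Under a uniform-dose
course every fraction shares one survival value S = exp(−A·N(d) + B), and
the entire volume trajectory depends on (A, B) only through that scalar.
The factors are then exactly unidentifiable along the ridge
−A·N(d) + B = const: the optimizer reaches a perfect fit anywhere on the
ridge.  A late dose change (e.g. a boost week) does not resolve it,
because after a handful of effective fractions the viable pool is
numerically annihilated and later doses leave no imprint on the volume.

Consequences drawn here:

- Parameter-recovery experiments use `recovery_design()`: five fractions
  at 3-day spacing with escalating doses 1–5 Gy and fourteen sample times
  through day 28, placing samples inside inter-fraction gaps while the
  viable/damaged mixture is still informative.  On that design, noiseless
  data pin (A, B) to ~1e−10 relative across A ∈ [0.2, 0.8], B ∈ [−3, −0.5].
  It is an identifiability experiment, not a clinical course.
- Round-trip tests under the realistic uniform 2 Gy × 25 regimen assert
  what is actually identifiable: the per-fraction log survival −A·N + B
  (recovered to ~1e−6) and a perfect R².
- Fitted (A, B) from clinical uniform-dose courses should be read as a
  ridge representative, informative through the combination −A·N + B only.
- Even on the identifiable design, 5% measurement noise leaves the ridge
  direction weakly constrained: Monte-Carlo medians of |Â − A| are of
  order 1 while −A·N + B stays within a few percent.  The package reports
  these error medians as computed rather than pretending the factors are
  well determined.

## Synthetic data

The generator emulates the published validation conditions: per-cohort
uniform draws of V₀ and T_half over the printed patient ranges (lung
7.6–189.3 cm³ and 33.3–50.2 d; cervix 8.0–375.2 cm³ and 13.9–90.6 d),
T_pot fixed per cohort, true A ∈ [0.15, 0.9] and B ∈ [−3, −0.4]
bracketing the nine published fits, a conventional 2 Gy × 25 course at 5
fractions/week with weekend gaps (the study never printed its schedules;
this is the standard course), and four volume samples at 14-day intervals
(three-to-four sequential CTs at one-to-two-week spacing, taking the
coarser end).  Measurement noise is multiplicative lognormal with median 1
and configurable CV (default 5%), since contouring error scales with
volume.  Identical seeds reproduce cohorts exactly; the noiseless
trajectory is seed-independent.

What the generator does *not* emulate: imaging and delineation as a
process (only its scalar noise), inter-fraction schedule deviations,
T_half measurement error (it is a known input here, estimated in
practice), hypoxic subpopulations or reoxygenation kinetics, and any
post-course change in growth behaviour.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not clinical accuracy.

## Numerical notes

- Survival exponents are evaluated directly in log space; underflow of S
  to 0 at extreme doses is accepted.
- The typed `CellState` enforces non-negative pools.  The simulation core
  used by the fitting objective works on raw floats because bound corners
  with S > 1 transiently drive the damaged pool negative; volumes remain
  provably positive there (viable·e^{λt} + dead·e^{−μt} ≥ total·e^{−μt} > 0
  segment by segment), so the least-squares surface stays finite and
  smooth for the optimizer.
- The geometric closed form guards the removable singularity at
  r = S·e^{(λ+μ)Δt} = 1.
- Grid/refinement sizes (21×21, 5 starts), the Monte-Carlo sizes (200
  replicates at 5% CV; 100 per noise level in the noise-scaling study) and
  the 100-patient nesting cohort are the package's chosen study sizes; a
  full test run takes about two minutes on one CPU.

## Limitations

- No uncertainty quantification beyond residuals (no bootstrap or profile
  likelihood); point estimates only, matching the estimation procedure the
  model was introduced with.
- T_pot and T_half are fixed inputs; co-fitting them would deepen the
  identifiability problems described above.
- No hypoxic compartment or reoxygenation; those mechanisms are folded
  into A and B by design.
- Absolute-volume least squares implicitly weights large early volumes
  more than small late ones; the relative switch inverts that emphasis.
  Neither is "correct" — the choice should follow the error structure of
  the volumetry.
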