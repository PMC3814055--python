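"""Synthetic patients with known ground-truth correction factors.

No volume trajectories from the published validation cohort are available,
so the fitting surface is exercised on synthetic patients instead: each
patient gets an initial volume, a clearance halving time, a cohort-specific
potential doubling time, true correction factors (A, B), a fractionation
schedule, and sparse sampling times mimicking sequential CT follow-up.  The
noiseless trajectory comes from the forward model itself; a noisy companion
multiplies each volume by an independent lognormal factor with median 1 and
a given coefficient of variation (CT-delineation error scales with volume,
hence multiplicative noise).

Defaults emulate the published study's conditions: per-cohort V0 and
T_half ranges spanning the printed patient tables, T_pot fixed per cohort
(5.5 d lung, 4.5 d cervix), a conventional 2 Gy x 25 course at 5
fractions/week, and 4 volume samples at 14-day intervals starting at the
baseline scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    KineticParams,
    TreatmentSchedule,
    VolumeSeries,
    expand_regimen,
    simulate_course,
)
from .exceptions import DomainError
from .reference import COHORTS
from .survival import DEFAULT_ALPHA, DEFAULT_BETA, RadiosensitivityParams

__all__ = [
    "SyntheticPatientSpec",
    "SyntheticPatient",
    "generate_trajectory",
    "generate_cohort",
    "recovery_design",
    "DEFAULT_SAMPLE_TIMES",
    "COHORT_RANGES",
]

#: Baseline + follow-up every 14 days, 4 samples (three-to-four sequential
#: CT sets at one-to-two-week spacing, taking the coarser end).
DEFAULT_SAMPLE_TIMES = (0.0, 14.0, 28.0, 42.0)

#: True-correction-factor draw ranges, bracketing the nine published fits.
DEFAULT_A_RANGE = (0.15, 0.9)
DEFAULT_B_RANGE = (-3.0, -0.4)

#: Per-cohort uniform draw ranges for V0 (cm^3) and T_half (days),
#: spanning the published per-cohort patient tables.
COHORT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    name: {
        "v0": (min(tab.v0), max(tab.v0)),
        "t_half": (min(tab.t_half), max(tab.t_half)),
    }
    for name, tab in COHORTS.items()
}


def recovery_design() -> tuple[TreatmentSchedule, tuple[float, ...]]:
    """Schedule and sampling times for parameter-recovery experiments.

    Under a uniform-dose course every fraction shares one surviving
    fraction ``S = exp(-A*N(d) + B)``, so the volume trajectory depends on
    (A, B) only through that scalar: A and B are structurally
    unidentifiable along the ridge ``-A*N(d) + B = const``.  Worse, once
    the cumulative kill is strong the viable pool is numerically
    annihilated and later fractions leave no imprint at all, so even a
    late dose change (a boost week) cannot separate the factors.

    A recovery study therefore needs dose variation *early* and samples
    inside the inter-fraction gaps, where the viable/damaged mixture is
    still informative.  This design uses five fractions at 3-day spacing
    with escalating doses 1..5 Gy and dense sampling through day 28; with
    it, noiseless data pin (A, B) to ~1e-10 relative across the plausible
    parameter range.  It is an identifiability experiment, not a clinical
    course.

    Returns
    -------
    (TreatmentSchedule, sample_times)
    """
    schedule = TreatmentSchedule.from_arrays(
        [0.0, 3.0, 6.0, 9.0, 12.0], [1.0, 2.0, 3.0, 4.0, 5.0]
    )
    sample_times = (
        0.0, 1.0, 2.0, 4.0, 5.0, 7.0, 8.0, 10.0, 11.0,
        13.0, 14.0, 17.0, 21.0, 28.0,
    )
    return schedule, sample_times


@dataclass(frozen=True)
class SyntheticPatientSpec:
    """Ground truth for one synthetic patient."""

    v0: float
    t_half: float
    t_pot: float
    true_corr_a: float
    true_corr_b: float
    schedule: TreatmentSchedule = field(default_factory=expand_regimen)
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    noise_cv: float = 0.05
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if not (self.v0 > 0.0):
            raise DomainError(f"v0 must be positive, got {self.v0}")
        if self.noise_cv < 0.0:
            raise DomainError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if min(self.sample_times) < 0.0:
            raise DomainError("sample times must not precede the series origin")
        # delegate remaining validation to the domain types
        KineticParams(t_pot=self.t_pot, t_half=self.t_half)
        RadiosensitivityParams(
            alpha=self.alpha, beta=self.beta,
            corr_a=self.true_corr_a, corr_b=self.true_corr_b,
        )

    @property
    def kinetics(self) -> KineticParams:
        return KineticParams(t_pot=self.t_pot, t_half=self.t_half)

    @property
    def radio(self) -> RadiosensitivityParams:
        return RadiosensitivityParams(
            alpha=self.alpha, beta=self.beta,
            corr_a=self.true_corr_a, corr_b=self.true_corr_b,
        )


@dataclass(frozen=True)
class SyntheticPatient:
    """A spec plus its generated noiseless and noisy trajectories."""

    spec: SyntheticPatientSpec
    noiseless: VolumeSeries
    noisy: VolumeSeries


def generate_trajectory(
    spec: SyntheticPatientSpec,
) -> tuple[VolumeSeries, VolumeSeries]:
    """Forward-simulate one synthetic patient.

    Returns ``(noiseless, noisy)``.  The noisy series multiplies each
    noiseless volume by an independent lognormal factor with median 1 and
    coefficient of variation ``spec.noise_cv`` (sigma^2 = ln(1 + cv^2)),
    drawn from ``numpy.random.default_rng(spec.seed)`` — identical seeds
    give identical output, and the noiseless series is seed-independent.
    """
    noiseless = simulate_course(
        spec.v0, spec.schedule, spec.radio, spec.kinetics,
        np.asarray(spec.sample_times, dtype=float),
    )
    if spec.noise_cv == 0.0:
        return noiseless, noiseless
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    factors = np.exp(sigma * rng.standard_normal(len(noiseless)))
    noisy = VolumeSeries(
        times=noiseless.times.copy(), volumes=noiseless.volumes * factors
    )
    return noiseless, noisy


def generate_cohort(
    n: int,
    cohort: str,
    seed: int,
    *,
    noise_cv: float = 0.05,
    a_range: tuple[float, float] = DEFAULT_A_RANGE,
    b_range: tuple[float, float] = DEFAULT_B_RANGE,
    schedule: TreatmentSchedule | None = None,
    sample_times: tuple[float, ...] = DEFAULT_SAMPLE_TIMES,
) -> list[SyntheticPatient]:
    """Draw ``n`` synthetic patients from a named cohort.

    V0 and T_half are drawn uniformly from the cohort's published ranges,
    the true (A, B) uniformly from ``a_range`` x ``b_range``; T_pot is the
    cohort's fixed value.  Per-patient noise seeds are derived from ``seed``
    via ``default_rng``, so a fixed seed reproduces the cohort exactly.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if cohort not in COHORTS:
        raise DomainError(
            f"unknown cohort {cohort!r}; expected one of {sorted(COHORTS)}"
        )
    tab = COHORTS[cohort]
    ranges = COHORT_RANGES[cohort]
    rng = np.random.default_rng(seed)
    patients: list[SyntheticPatient] = []
    for _ in range(n):
        spec = SyntheticPatientSpec(
            v0=float(rng.uniform(*ranges["v0"])),
            t_half=float(rng.uniform(*ranges["t_half"])),
            t_pot=tab.t_pot,
            true_corr_a=float(rng.uniform(*a_range)),
            true_corr_b=float(rng.uniform(*b_range)),
            schedule=schedule if schedule is not None else expand_regimen(),
            sample_times=tuple(sample_times),
            noise_cv=noise_cv,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        noiseless, noisy = generate_trajectory(spec)
        patients.append(SyntheticPatient(spec=spec, noiseless=noiseless, noisy=noisy))
    return patients
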