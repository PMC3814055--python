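"""Two-compartment tumor cell-population kinetics over a fractionated course.

The tumor is modelled as two well-mixed pools of cells: viable
(proliferating) and lethally damaged (doomed but still occupying volume).
Each dose fraction instantaneously moves a fraction ``1 - S`` of the viable
pool into the damaged pool, where ``S`` is the surviving fraction from
:mod:`tumorlq.survival`.  Between events the pools evolve exponentially:

    viable(t + dt)  = viable(t)  * exp(+lambda * dt),   lambda = ln2 / T_pot
    damaged(t + dt) = damaged(t) * exp(-mu * dt),       mu     = ln2 / T_half

``T_pot`` is the potential doubling time of the viable population and
``T_half`` the clearance halving time of lethally damaged cells (both in
days; all times in this package are days).  Tumor volume is proportional to
the total cell count, so states are normalized to total = 1 at t = 0 (the
whole population viable) and the measured initial volume ``v0`` carries the
scale:  V(t) = v0 * (viable(t) + damaged(t)).

Evaluation at arbitrary times applies the same exponential laws over the
partial interval since the most recent event; when an evaluation time
coincides with a fraction time, the fraction is applied first
("post-fraction" convention).  After the final fraction, viable regrowth at
rate lambda continues indefinitely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import DomainError
from .survival import RadiosensitivityParams, survival_fraction

__all__ = [
    "KineticParams",
    "Fraction",
    "TreatmentSchedule",
    "CellState",
    "VolumeSeries",
    "growth_rate",
    "decay_rate",
    "apply_fraction",
    "evolve_interval",
    "simulate_course",
    "state_at",
    "expand_regimen",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class KineticParams:
    """Population kinetics: potential doubling time and clearance halving time.

    Both in days, both strictly positive.
    """

    t_pot: float
    t_half: float

    def __post_init__(self) -> None:
        if not (self.t_pot > 0.0 and math.isfinite(self.t_pot)):
            raise DomainError(f"t_pot must be positive and finite, got {self.t_pot}")
        if not (self.t_half > 0.0 and math.isfinite(self.t_half)):
            raise DomainError(f"t_half must be positive and finite, got {self.t_half}")

    @property
    def lam(self) -> float:
        """Proliferation rate constant, per day."""
        return _LN2 / self.t_pot

    @property
    def mu(self) -> float:
        """Damaged-cell clearance rate constant, per day."""
        return _LN2 / self.t_half


def growth_rate(kinetics: KineticParams) -> float:
    """Viable-pool exponential growth constant lambda = ln2 / T_pot (per day)."""
    return kinetics.lam


def decay_rate(kinetics: KineticParams) -> float:
    """Damaged-pool exponential decay constant mu = ln2 / T_half (per day)."""
    return kinetics.mu


class Fraction(NamedTuple):
    """A single dose fraction: delivery time (days) and dose (Gy)."""

    time: float
    dose: float


@dataclass(frozen=True)
class TreatmentSchedule:
    """An ordered sequence of dose fractions with strictly increasing times."""

    fractions: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        fracs = tuple(Fraction(float(t), float(d)) for t, d in self.fractions)
        object.__setattr__(self, "fractions", fracs)
        for i, f in enumerate(fracs):
            if f.time < 0.0:
                raise DomainError(f"fraction {i}: time {f.time} is negative")
            if not (f.dose > 0.0):
                raise DomainError(f"fraction {i}: dose {f.dose} is not positive")
            if i > 0 and not (f.time > fracs[i - 1].time):
                raise DomainError(
                    f"fraction times must be strictly increasing; "
                    f"fraction {i} at t={f.time} follows t={fracs[i - 1].time}"
                )

    @classmethod
    def from_arrays(
        cls, times: Sequence[float], doses: Sequence[float]
    ) -> "TreatmentSchedule":
        if len(times) != len(doses):
            raise DomainError("times and doses must have equal length")
        return cls(tuple(Fraction(float(t), float(d)) for t, d in zip(times, doses)))

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.fractions], dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.array([f.dose for f in self.fractions], dtype=float)

    def __len__(self) -> int:
        return len(self.fractions)


def expand_regimen(
    n_fractions: int = 25,
    dose_gy: float = 2.0,
    fractions_per_week: int = 5,
    start_day: float = 0.0,
) -> TreatmentSchedule:
    """Expand a shorthand regimen into an explicit schedule.

    Fractions are delivered once daily on the first ``fractions_per_week``
    days of each 7-day week (weekend gaps), starting at ``start_day``.
    The default is the conventional 2 Gy x 25, 5 fractions/week course.
    """
    if n_fractions < 1:
        raise DomainError(f"n_fractions must be >= 1, got {n_fractions}")
    if not (1 <= fractions_per_week <= 7):
        raise DomainError(
            f"fractions_per_week must be in 1..7, got {fractions_per_week}"
        )
    times = [
        start_day + 7.0 * (i // fractions_per_week) + (i % fractions_per_week)
        for i in range(n_fractions)
    ]
    return TreatmentSchedule.from_arrays(times, [dose_gy] * n_fractions)


@dataclass(frozen=True)
class CellState:
    """Relative viable / lethally damaged cell counts (dimensionless).

    Normalized so the pre-treatment total is 1; volume = total x v0.
    """

    n_viable: float
    n_dead: float

    def __post_init__(self) -> None:
        if not (self.n_viable >= 0.0 and math.isfinite(self.n_viable)):
            raise DomainError(f"n_viable must be >= 0 and finite, got {self.n_viable}")
        if not (self.n_dead >= 0.0 and math.isfinite(self.n_dead)):
            raise DomainError(f"n_dead must be >= 0 and finite, got {self.n_dead}")

    @property
    def total(self) -> float:
        return self.n_viable + self.n_dead


@dataclass(frozen=True)
class VolumeSeries:
    """Paired observation times (days) and tumor volumes (cm^3)."""

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size < 1:
            raise DomainError(
                f"times and volumes must be equal-length 1-D arrays of length >= 1, "
                f"got shapes {t.shape} and {v.shape}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise DomainError("times and volumes must be finite")
        if np.any(np.diff(t) < 0.0):
            raise DomainError("times must be non-decreasing")
        if np.any(v <= 0.0):
            raise DomainError("volumes must be positive")
        t.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)

    def __len__(self) -> int:
        return self.times.size


def apply_fraction(state: CellState, s: float) -> CellState:
    """Instantaneous effect of one dose fraction with surviving fraction ``s``.

    The viable pool is multiplied by ``s``; the killed complement
    ``(1 - s) * n_viable`` moves to the damaged pool.  Total count is
    conserved exactly at the instant of irradiation.  ``s`` must be positive;
    values above 1 are ill-posed and will fail the damaged-pool invariant
    once it would go negative.
    """
    if not (s > 0.0):
        raise DomainError(f"survival fraction must be positive, got {s}")
    killed = state.n_viable * (1.0 - s)
    return CellState(n_viable=state.n_viable * s, n_dead=state.n_dead + killed)


def evolve_interval(state: CellState, kinetics: KineticParams, dt: float) -> CellState:
    """Free evolution over ``dt`` days: viable grows, damaged clears."""
    if dt < 0.0:
        raise DomainError(f"dt must be non-negative, got {dt}")
    return CellState(
        n_viable=state.n_viable * math.exp(kinetics.lam * dt),
        n_dead=state.n_dead * math.exp(-kinetics.mu * dt),
    )


def _trace(
    frac_times: np.ndarray,
    frac_survivals: np.ndarray,
    lam: float,
    mu: float,
    eval_times: np.ndarray,
    nv0: float = 1.0,
    nd0: float = 0.0,
    t0: float = 0.0,
    resumed: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Walk the event timeline; return (viable, damaged) at each eval time.

    Raw-float core shared by :func:`simulate_course` and the fitting
    objective.  Performs no state validation: the fitting layer legitimately
    explores survival > 1 corners where the damaged pool goes negative
    (volumes remain positive there; see module docstring of
    :mod:`tumorlq.fitting`).  Fractions before t0 are skipped; a fraction
    exactly at t0 is applied on a fresh start but skipped when ``resumed``
    (the supplied state is post-fraction by convention).
    """
    nv, nd, t = nv0, nd0, t0
    out_v = np.empty(eval_times.size)
    out_d = np.empty(eval_times.size)
    side = "right" if resumed else "left"
    i = int(np.searchsorted(frac_times, t0, side=side))
    nf = frac_times.size
    exp = math.exp
    for j, te in enumerate(eval_times):
        while i < nf and frac_times[i] <= te:
            dt = frac_times[i] - t
            nv *= exp(lam * dt)
            nd *= exp(-mu * dt)
            s = frac_survivals[i]
            nd += nv * (1.0 - s)
            nv *= s
            t = frac_times[i]
            i += 1
        dt = te - t
        out_v[j] = nv * exp(lam * dt)
        out_d[j] = nd * exp(-mu * dt)
    return out_v, out_d


def simulate_course(
    v0: float,
    schedule: TreatmentSchedule,
    radio: RadiosensitivityParams,
    kinetics: KineticParams,
    eval_times: Sequence[float],
    *,
    initial_state: CellState | None = None,
    t_start: float = 0.0,
) -> VolumeSeries:
    """Tumor volume trajectory under a fractionated course.

    Parameters
    ----------
    v0 : float
        Volume scale in cm^3: the measured volume at the series origin
        (where the normalized total count is 1).
    schedule : TreatmentSchedule
        Fraction times (days, on the same axis as ``eval_times``) and doses.
    radio, kinetics :
        Survival and population-kinetics parameters.
    eval_times : sequence of float
        Sorted times (days, >= ``t_start``) at which to report the volume.
        At a time coinciding with a fraction the post-fraction volume is
        reported.
    initial_state, t_start :
        Resume support: state at ``t_start`` (default: all-viable total 1
        at t = 0).  When an initial state is supplied it is taken to be
        post-fraction, so fractions at times <= ``t_start`` are treated as
        already applied; on a fresh start a fraction exactly at t = 0 is
        applied.  Simulating 0..t in one call equals simulating 0..t' and
        resuming from the returned state at t'.

    Returns
    -------
    VolumeSeries
        ``V(t) = v0 * (n_viable(t) + n_dead(t))`` at each requested time.
    """
    if not (v0 > 0.0):
        raise DomainError(f"v0 must be positive, got {v0}")
    et = np.asarray(eval_times, dtype=float)
    if et.ndim != 1 or et.size < 1:
        raise DomainError("eval_times must be a non-empty 1-D sequence")
    if np.any(np.diff(et) < 0.0):
        raise DomainError("eval_times must be sorted non-decreasing")
    if et[0] < t_start:
        raise DomainError(
            f"eval time {et[0]} precedes the series origin t={t_start}"
        )
    state = initial_state if initial_state is not None else CellState(1.0, 0.0)
    surv = np.array(
        [survival_fraction(radio, f.dose) for f in schedule.fractions], dtype=float
    )
    nv, nd = _trace(
        schedule.times, surv, kinetics.lam, kinetics.mu, et,
        nv0=state.n_viable, nd0=state.n_dead, t0=t_start,
        resumed=initial_state is not None,
    )
    return VolumeSeries(times=et, volumes=v0 * (nv + nd))


def state_at(
    schedule: TreatmentSchedule,
    radio: RadiosensitivityParams,
    kinetics: KineticParams,
    t: float,
    *,
    initial_state: CellState | None = None,
    t_start: float = 0.0,
) -> CellState:
    """Normalized cell state at time ``t`` (post-fraction if ``t`` is a
    fraction time); companion to :func:`simulate_course` for resuming."""
    state = initial_state if initial_state is not None else CellState(1.0, 0.0)
    if t < t_start:
        raise DomainError(f"t={t} precedes t_start={t_start}")
    surv = np.array(
        [survival_fraction(radio, f.dose) for f in schedule.fractions], dtype=float
    )
    nv, nd = _trace(
        schedule.times, surv, kinetics.lam, kinetics.mu,
        np.array([t], dtype=float),
        nv0=state.n_viable, nd0=state.n_dead, t0=t_start,
        resumed=initial_state is not None,
    )
    return CellState(n_viable=float(nv[0]), n_dead=float(nd[0]))
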