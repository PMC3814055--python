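"""Published nine-patient validation cohort values.

The two-compartment corrected-survival model was validated on a published
clinical cohort of four lung and five cervical cancer patients.  The study
printed, per patient: the initial tumor volume V0 (cm^3) and the
damaged-cell clearance halving time T_half (days), and the fitted
correction factors A, B with the goodness-of-fit scores R^2 (corrected
model) and R0^2 (conventional comparator).  The underlying volume
trajectories and fraction schedules were not published, so these tables are
the anchor for cohort-level arithmetic and for the synthetic generator's
default parameter ranges — not a dataset the per-patient fits can be
recomputed from.

Potential doubling times used in that study: T_pot = 5.5 days for lung
tumors and 4.5 days for cervical tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CohortTable", "LUNG_COHORT", "CERVIX_COHORT", "COHORTS"]


@dataclass(frozen=True)
class CohortTable:
    """Per-patient published values for one cohort (parallel tuples)."""

    name: str
    t_pot: float
    v0: tuple[float, ...]
    t_half: tuple[float, ...]
    corr_a: tuple[float, ...]
    corr_b: tuple[float, ...]
    r2_new: tuple[float, ...]
    r2_conventional: tuple[float, ...]

    @property
    def n_patients(self) -> int:
        return len(self.v0)


LUNG_COHORT = CohortTable(
    name="lung",
    t_pot=5.5,
    v0=(7.6, 27.4, 97.7, 189.3),
    t_half=(42.5, 35.9, 50.2, 33.3),
    corr_a=(0.85, 0.82, 0.66, 0.82),
    corr_b=(-2.03, -2.10, -2.01, -0.41),
    r2_new=(0.99, 0.89, 0.91, 0.97),
    r2_conventional=(0.52, 0.43, -0.68, 0.94),
)

CERVIX_COHORT = CohortTable(
    name="cervix",
    t_pot=4.5,
    v0=(8.0, 14.2, 22.1, 76.1, 375.2),
    t_half=(13.9, 90.6, 15.6, 24.4, 31.0),
    corr_a=(0.43, 0.19, 0.24, 0.74, 0.17),
    corr_b=(-1.66, -2.95, -1.78, -0.71, -0.63),
    r2_new=(0.99, 0.87, 0.99, 0.95, 0.87),
    r2_conventional=(0.92, -1.43, 0.87, 0.81, 0.87),
)

COHORTS: dict[str, CohortTable] = {
    "lung": LUNG_COHORT,
    "cervix": CERVIX_COHORT,
}
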