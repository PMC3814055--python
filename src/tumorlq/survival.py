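"""Cell-survival mathematics.

The conventional linear-quadratic (LQ) model writes the surviving fraction
after a single dose D as

    S = exp(-(alpha*D + beta*D**2)),

where ``alpha*D + beta*D**2`` is the mean number of lethal events per cell
(alpha: single-track lethal events per Gy; beta: two-track sublethal
accumulation per Gy^2).  The corrected model used throughout this package
introduces two dimensionless correction factors:

    S = exp(-A*(alpha*D + beta*D**2) + B)

``A`` rescales the double-strand-break term (hypoxia, potentially lethal
damage repair, microenvironment); ``B`` adds kill not captured by alpha/beta
events (e.g. single-strand breaks leading to reproductive death).  Setting
A = 1, B = 0 recovers the conventional model exactly.

Because A multiplies ``alpha*D + beta*D**2``, a fitted A is only meaningful
relative to the assumed (alpha, beta): halving alpha and beta while doubling
A leaves every survival value unchanged.  The package therefore treats
alpha and beta as required configuration, with documented defaults
alpha = 0.35 / Gy and alpha/beta = 10 Gy (beta = 0.035 / Gy^2), standard
literature values for tumors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import DomainError

__all__ = [
    "RadiosensitivityParams",
    "SupraUnitySurvivalWarning",
    "mean_lethal_events",
    "survival_fraction",
    "conventional_survival",
]

#: Default linear sensitivity, per Gy (generic tumor value).
DEFAULT_ALPHA = 0.35
#: Default quadratic sensitivity, per Gy^2 (alpha/beta = 10 Gy).
DEFAULT_BETA = 0.035


class SupraUnitySurvivalWarning(UserWarning):
    """The corrected survival fraction exceeded 1 (ill-posed A, B region)."""


@dataclass(frozen=True)
class RadiosensitivityParams:
    """LQ sensitivities plus the multiplicative/additive correction factors.

    Parameters
    ----------
    alpha : float
        Linear sensitivity coefficient, per Gy.  Must be >= 0.
    beta : float
        Quadratic sensitivity coefficient, per Gy^2.  Must be >= 0.
        ``alpha`` and ``beta`` may not both be zero.
    corr_a : float
        Multiplicative correction factor A (> 0).  Default 1 (conventional).
    corr_b : float
        Additive correction factor B, any real.  Fitted values on clinical
        cohorts are typically negative, but the model does not constrain
        the sign.  Default 0 (conventional).
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    corr_a: float = 1.0
    corr_b: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha >= 0.0) or not (self.beta >= 0.0):
            raise DomainError(
                f"alpha and beta must be non-negative, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )
        if self.alpha == 0.0 and self.beta == 0.0:
            raise DomainError("alpha and beta may not both be zero")
        if not (self.corr_a > 0.0):
            raise DomainError(f"corr_a must be positive, got {self.corr_a}")
        if not math.isfinite(self.corr_b):
            raise DomainError(f"corr_b must be finite, got {self.corr_b}")


def mean_lethal_events(params: RadiosensitivityParams, dose: float) -> float:
    """Mean number of lethal events per cell at ``dose`` Gy.

    Returns ``alpha*D + beta*D**2`` — the uncorrected LQ event count.
    The A/B corrections apply to survival, not to the event count.
    """
    if dose < 0.0:
        raise DomainError(f"dose must be non-negative, got {dose}")
    return params.alpha * dose + params.beta * dose * dose


def survival_fraction(params: RadiosensitivityParams, dose: float) -> float:
    """Corrected surviving fraction ``exp(-A*(alpha*D + beta*D**2) + B)``.

    The exponent is evaluated in log space; underflow to 0.0 at extreme
    doses is allowed.  The result is not clamped to <= 1: combinations with
    B > 0 (or B >= 0 at zero dose) can yield S > 1, which is an ill-posed
    parameter region rather than a numerical accident, so a
    :class:`SupraUnitySurvivalWarning` is emitted and the value returned
    as computed.  Bounding S is the fitting layer's job.
    """
    n = mean_lethal_events(params, dose)
    s = math.exp(-params.corr_a * n + params.corr_b)
    if s > 1.0:
        warnings.warn(
            f"survival fraction {s:.6g} exceeds 1 at dose {dose} Gy "
            f"(corr_a={params.corr_a}, corr_b={params.corr_b}); "
            "the parameter combination is ill-posed",
            SupraUnitySurvivalWarning,
            stacklevel=2,
        )
    return s


def conventional_survival(alpha: float, beta: float, dose: float) -> float:
    """Conventional LQ surviving fraction ``exp(-(alpha*D + beta*D**2))``.

    Identical to :func:`survival_fraction` with A = 1, B = 0; always in
    (0, 1] (up to underflow to 0 at extreme doses).
    """
    params = RadiosensitivityParams(alpha=alpha, beta=beta, corr_a=1.0, corr_b=0.0)
    if dose < 0.0:
        raise DomainError(f"dose must be non-negative, got {dose}")
    return math.exp(-(params.alpha * dose + params.beta * dose * dose))
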