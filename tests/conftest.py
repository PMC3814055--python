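import numpy as np
import pytest

from tumorlq import (
    KineticParams,
    RadiosensitivityParams,
    TreatmentSchedule,
    expand_regimen,
)


@pytest.fixture
def default_radio() -> RadiosensitivityParams:
    """Generic tumor sensitivities with a clinically plausible correction."""
    return RadiosensitivityParams(alpha=0.35, beta=0.035, corr_a=0.6, corr_b=-1.5)


@pytest.fixture
def lung_kinetics() -> KineticParams:
    return KineticParams(t_pot=5.5, t_half=40.0)


@pytest.fixture
def standard_course() -> TreatmentSchedule:
    """Conventional 2 Gy x 25, 5 fractions/week."""
    return expand_regimen()


@pytest.fixture
def uniform_daily_course() -> TreatmentSchedule:
    """30 daily 2 Gy fractions with no weekend gaps (closed-form territory)."""
    return TreatmentSchedule.from_arrays(np.arange(30.0), np.full(30, 2.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
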