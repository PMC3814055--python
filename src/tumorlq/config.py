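"""Run configuration: flat keys, documented defaults, YAML loading.

Every field has a default, so an empty (or absent) config file is valid.
The effective config is echoed verbatim into every output record for
provenance.  Precedence when used from the CLI: command-line flags override
the config file, which overrides these defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ParseError

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration record.

    Units: alpha per Gy, beta per Gy^2, times in days, volumes in cm^3.
    ``t_pot``/``t_half`` defaults are the lung-cohort values (T_pot from the
    published study; T_half the lung cohort mean) and normally come from the
    per-patient config instead.
    """

    alpha: float = 0.35
    beta: float = 0.035
    t_pot: float = 5.5
    t_half: float = 40.5
    bounds_a_lo: float = 0.01
    bounds_a_hi: float = 3.0
    bounds_b_lo: float = -5.0
    bounds_b_hi: float = 1.0
    grid_size: int = 21
    n_starts: int = 5
    residual_space: str = "absolute"
    n_fractions: int = 25
    dose_gy: float = 2.0
    fractions_per_week: int = 5
    noise_cv: float = 0.05
    sample_interval_days: float = 14.0
    n_samples: int = 4
    log_level: str = "INFO"
    seed: int = 0

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def bounds_a(self) -> tuple[float, float]:
        return (self.bounds_a_lo, self.bounds_a_hi)

    @property
    def bounds_b(self) -> tuple[float, float]:
        return (self.bounds_b_lo, self.bounds_b_hi)


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Unknown keys are rejected with a message naming them; an empty file
    yields the defaults.  ``overrides`` (e.g. CLI flags) take precedence
    over file values; ``None`` overrides are ignored.
    """
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ParseError(f"config file {path} must contain a mapping")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ParseError(
            f"unknown config key(s): {', '.join(unknown)}; "
            f"valid keys: {', '.join(sorted(valid))}"
        )
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"invalid config value: {exc}") from exc
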