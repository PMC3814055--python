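"""CSV and JSON round-tripping for schedules, volume series and fit records.

CSV dialects (header required, times in days):

* volume series — ``time_days,volume_cm3``
* schedule      — ``time_days,dose_gy``

Lines starting with ``#`` are provenance comments (package version and the
effective config) written by the CLI; readers skip them.  Floats are
serialized at full precision, so a write-then-read round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from ._version import __version__
from .dynamics import TreatmentSchedule, VolumeSeries
from .exceptions import ParseError
from .fitting import FitResult

__all__ = [
    "read_volume_series",
    "write_volume_series",
    "read_schedule",
    "write_schedule",
    "provenance",
    "write_fit_record",
]

VOLUME_COLUMNS = ("time_days", "volume_cm3")
SCHEDULE_COLUMNS = ("time_days", "dose_gy")


def provenance(config: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Provenance block embedded in every artifact this module writes."""
    return {
        "package": "tumorlq",
        "version": __version__,
        "config": dict(config) if config is not None else {},
    }


def _read_two_column_csv(path: str | Path, columns: tuple[str, str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: could not parse CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {','.join(columns)}"
        )
    for col in columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} in column "
                f"{col!r} at data row {int(bad[0]) + 1}"
            )
        if numeric.isna().any():
            row = int(df.index[numeric.isna()][0]) + 1
            raise ParseError(f"{path}: empty cell in column {col!r} at data row {row}")
        df[col] = numeric.astype(float)
    if len(df) < 1:
        raise ParseError(f"{path}: no data rows")
    return df


def read_volume_series(path: str | Path) -> VolumeSeries:
    """Read and validate a ``time_days,volume_cm3`` CSV."""
    df = _read_two_column_csv(path, VOLUME_COLUMNS)
    t = df["time_days"].to_numpy()
    v = df["volume_cm3"].to_numpy()
    bad = np.flatnonzero(v <= 0.0)
    if bad.size:
        raise ParseError(
            f"{path}: non-positive volume {v[bad[0]]} at data row {bad[0] + 1}"
        )
    if np.any(np.diff(t) < 0.0):
        row = int(np.flatnonzero(np.diff(t) < 0.0)[0]) + 2
        raise ParseError(f"{path}: times not sorted at data row {row}")
    return VolumeSeries(times=t, volumes=v)


def _write_csv(
    df: pd.DataFrame, path: str | Path, config: Mapping[str, Any] | None
) -> None:
    path = Path(path)
    prov = provenance(config)
    with path.open("w") as fh:
        fh.write(f"# package: {prov['package']} {prov['version']}\n")
        for key, val in prov["config"].items():
            fh.write(f"# config {key}: {val}\n")
        df.to_csv(fh, index=False)


def write_volume_series(
    series: VolumeSeries,
    path: str | Path,
    *,
    config: Mapping[str, Any] | None = None,
) -> None:
    df = pd.DataFrame(
        {"time_days": series.times, "volume_cm3": series.volumes}
    )
    _write_csv(df, path, config)


def read_schedule(path: str | Path) -> TreatmentSchedule:
    """Read and validate a ``time_days,dose_gy`` CSV."""
    df = _read_two_column_csv(path, SCHEDULE_COLUMNS)
    t = df["time_days"].to_numpy()
    d = df["dose_gy"].to_numpy()
    bad = np.flatnonzero(d <= 0.0)
    if bad.size:
        raise ParseError(
            f"{path}: non-positive dose {d[bad[0]]} at data row {bad[0] + 1}"
        )
    if np.any(np.diff(t) <= 0.0):
        row = int(np.flatnonzero(np.diff(t) <= 0.0)[0]) + 2
        raise ParseError(
            f"{path}: fraction times not strictly increasing at data row {row}"
        )
    return TreatmentSchedule.from_arrays(t, d)


def write_schedule(
    schedule: TreatmentSchedule,
    path: str | Path,
    *,
    config: Mapping[str, Any] | None = None,
) -> None:
    df = pd.DataFrame({"time_days": schedule.times, "dose_gy": schedule.doses})
    _write_csv(df, path, config)


def write_fit_record(
    path: str | Path,
    fit: FitResult,
    *,
    config: Mapping[str, Any],
    measured: VolumeSeries,
    predicted: VolumeSeries | None = None,
    r0_squared: float | None = None,
    bounds_a: tuple[float, float] | None = None,
    bounds_b: tuple[float, float] | None = None,
) -> dict[str, Any]:
    """Write a JSON fit record (returned as a dict as well).

    Includes the fitted parameters, scores, residuals, bounds and the full
    effective config + package version for provenance.
    """
    record: dict[str, Any] = {
        "provenance": provenance(config),
        "corr_a_hat": fit.corr_a_hat,
        "corr_b_hat": fit.corr_b_hat,
        "r_squared": fit.r_squared,
        "objective": fit.objective,
        "converged": fit.converged,
        "n_starts_used": fit.n_starts_used,
        "residuals_cm3": [float(r) for r in fit.residuals],
        "measured": {
            "time_days": [float(t) for t in measured.times],
            "volume_cm3": [float(v) for v in measured.volumes],
        },
    }
    if predicted is not None:
        record["predicted_volume_cm3"] = [float(v) for v in predicted.volumes]
    if r0_squared is not None:
        record["r0_squared"] = r0_squared
    if bounds_a is not None:
        record["bounds_a"] = list(bounds_a)
    if bounds_b is not None:
        record["bounds_b"] = list(bounds_b)
    Path(path).write_text(json.dumps(record, indent=2) + "\n")
    return record
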