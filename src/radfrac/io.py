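"""Cohorts, configuration and result serialization.

Virtual patients travel as JSON/YAML lists of parameter records; the
seven-patient fixture cohort the simulator was demonstrated on is
available under the name ``"table1"``.  Trajectories are written as CSV
(header ``day,dose_Gy,V_a,V_n,V_t,PO2,alpha,SF_t,SF_v,k``, volumes in %
of the initial volume, one row per day including day 0) or as JSON with
full-precision round-tripping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .errors import InvalidParameterError, RadfracError
from .model import (
    PatientParameters,
    SimulationResult,
    TRAJECTORY_COLUMNS,
)
from .schedule import FractionationSchedule

__all__ = [
    "TABLE1_COHORT",
    "load_cohort",
    "write_cohort",
    "load_schedule",
    "write_schedule",
    "write_result",
    "read_result",
    "load_series_frame",
    "RunConfig",
]

#: The seven-patient fixture cohort (fitted parameter signatures).
TABLE1_COHORT: tuple[PatientParameters, ...] = (
    PatientParameters("A", rho=0.17, t_half=14.0, k_hat=220.0, gamma_v=0.9),
    PatientParameters("B", rho=0.07, t_half=28.0, k_hat=150.0, gamma_v=0.7),
    PatientParameters("C", rho=0.08, t_half=4.0, k_hat=125.0, gamma_v=0.7),
    PatientParameters("D", rho=0.02, t_half=22.0, k_hat=300.0, gamma_v=0.9),
    PatientParameters("E", rho=0.02, t_half=30.0, k_hat=140.0, gamma_v=0.8),
    PatientParameters("F", rho=0.10, t_half=30.0, k_hat=120.0, gamma_v=0.6),
    PatientParameters("G", rho=0.10, t_half=30.0, k_hat=120.0, gamma_v=0.7),
)


def _cohort_from_records(records: Sequence[dict], strict: bool) -> list[PatientParameters]:
    if not records:
        raise InvalidParameterError("cohort is empty")
    cohort = []
    for i, rec in enumerate(records):
        try:
            params = PatientParameters(
                id=str(rec.get("id", i)),
                rho=float(rec["rho"]),
                t_half=float(rec["t_half"]),
                k_hat=float(rec["k_hat"]),
                gamma_v=float(rec["gamma_v"]),
            )
        except KeyError as exc:
            raise InvalidParameterError(f"cohort entry {i} missing field {exc}") from exc
        for msg in params.check_bounds(strict=strict):
            warnings.warn(msg, stacklevel=3)
        cohort.append(params)
    return cohort


def load_cohort(source: Any, strict: bool = True) -> list[PatientParameters]:
    """Load a cohort from the fixture name, a JSON/YAML file, or records.

    ``source`` may be the string ``"table1"`` (the shipped seven-patient
    fixture), a path to a ``.json``/``.yaml``/``.yml`` file containing a
    list of ``{id, rho, t_half, k_hat, gamma_v}`` records, or such a list
    directly.  Parameters outside the training bounds raise in strict
    mode and warn otherwise.
    """
    if isinstance(source, str) and source == "table1":
        return list(TABLE1_COHORT)
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            text = path.read_text()
        except OSError as exc:
            raise RadfracError(f"cannot read cohort file {path}: {exc}") from exc
        if path.suffix.lower() in (".yaml", ".yml"):
            records = yaml.safe_load(text)
        elif path.suffix.lower() == ".json":
            records = json.loads(text)
        else:
            raise InvalidParameterError(
                f"unsupported cohort file type {path.suffix!r} (use .json/.yaml)"
            )
        if not isinstance(records, list):
            raise InvalidParameterError(f"cohort file {path} must contain a list")
        return _cohort_from_records(records, strict)
    if isinstance(source, Sequence):
        return _cohort_from_records(list(source), strict)
    raise InvalidParameterError(f"cannot interpret cohort source {source!r}")


def write_cohort(cohort: Iterable[PatientParameters], path: str | Path) -> None:
    """Write a cohort as a JSON list of parameter records."""
    path = Path(path)
    records = [asdict(p) for p in cohort]
    path.write_text(json.dumps(records, indent=2) + "\n")


def load_schedule(path: str | Path) -> FractionationSchedule:
    """Read a schedule from a two-column CSV (``day,dose_Gy``)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = {"day", "dose_Gy"} - set(frame.columns)
    if missing:
        raise InvalidParameterError(f"schedule file {path} missing columns {sorted(missing)}")
    fractions = tuple(
        (int(day), float(dose)) for day, dose in zip(frame["day"], frame["dose_Gy"])
    )
    return FractionationSchedule(fractions=fractions, label=path.stem)


def write_schedule(schedule: FractionationSchedule, path: str | Path) -> None:
    """Write a schedule as a two-column CSV (``day,dose_Gy``)."""
    frame = pd.DataFrame(schedule.fractions, columns=["day", "dose_Gy"])
    frame.to_csv(path, index=False)


def write_result(result: SimulationResult, path: str | Path, format: str = "csv") -> None:
    """Serialize a simulation result.

    CSV writes the daily trajectory with the canonical header at 6
    significant digits; JSON writes parameters, endpoint and trajectories
    at full precision (read back with :func:`read_result`).
    """
    path = Path(path)
    try:
        if format == "csv":
            result.frame.to_csv(path, index=False, float_format="%.6g")
        elif format == "json":
            payload = {
                "params": asdict(result.params),
                "t_e": result.t_e,
                "schedule_label": result.schedule_label,
                "trajectory": {
                    col: result.frame[col].tolist() for col in TRAJECTORY_COLUMNS
                },
            }
            path.write_text(json.dumps(payload) + "\n")
        else:
            raise InvalidParameterError(f"unknown result format {format!r} (csv|json)")
    except OSError as exc:
        raise RadfracError(f"cannot write result to {path}: {exc}") from exc


def read_result(path: str | Path) -> SimulationResult:
    """Read back a JSON result written by :func:`write_result`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except OSError as exc:
        raise RadfracError(f"cannot read result from {path}: {exc}") from exc
    frame = pd.DataFrame(payload["trajectory"], columns=list(TRAJECTORY_COLUMNS))
    frame["day"] = frame["day"].astype(int)
    return SimulationResult(
        params=PatientParameters(**payload["params"]),
        frame=frame,
        t_e=int(payload["t_e"]),
        schedule_label=payload.get("schedule_label", ""),
    )


def load_series_frame(path: str | Path) -> pd.DataFrame:
    """Read a tumor-volume series CSV with columns ``day,V_t``."""
    frame = pd.read_csv(path)
    missing = {"day", "V_t"} - set(frame.columns)
    if missing:
        raise InvalidParameterError(f"series file {path} missing columns {sorted(missing)}")
    return frame


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a CLI run."""

    cohort: str = "table1"
    endpoint: str = "active"
    threshold: float = 20.0
    target_bed: float = 60.0
    clearance: str = "compound"
    mass_conserving: bool = False
    relaxed_bounds: bool = False
    seed: int | None = None
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.endpoint not in ("active", "total"):
            raise InvalidParameterError(
                f"endpoint must be 'active' or 'total', got {self.endpoint!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise InvalidParameterError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
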