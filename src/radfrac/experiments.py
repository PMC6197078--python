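"""The in silico fractionation study.

Given a cohort of virtual patients (parameter signatures fitted to real
tumor-volume series), this module runs the comparisons the simulator was
built for:

* a constant-dose grid (1-3 Gy/fraction, every arm at BED closest to
  60 Gy) with final active/total volumes, the dose-response Pearson
  correlation c(d, V), and the per-patient best dose;
* classification of the best dose as hypo-, standard or
  hyper-fractionation;
* the minimum-BED early-stop criterion: the cumulative BED delivered by
  the time the active volume first drops below a threshold (80%
  regression by default);
* the proliferation saturation index PSI = V(0) / k_hat;
* the ramp-order comparison: identical dose multisets delivered in
  increasing vs decreasing order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, UndefinedCorrelationError
from .model import (
    DEFAULT_CONSTANTS,
    DEFAULT_OPTIONS,
    ModelConstants,
    ModelOptions,
    PatientParameters,
    SimulationResult,
    simulate,
)
from .schedule import FractionationSchedule, constant_schedule, ramp_schedule

__all__ = [
    "DOSE_GRID",
    "RegimenOutcome",
    "PartialBedOutcome",
    "DoseGridResult",
    "RampComparison",
    "run_dose_grid",
    "dose_response_correlation",
    "classify_regimen",
    "min_bed_to_threshold",
    "psi",
    "ramp_comparison",
]

#: Constant-dose arms of the study, Gy per fraction.
DOSE_GRID: tuple[float, ...] = (1.0, 1.5, 1.8, 2.0, 2.5, 3.0)

#: Doses considered standard fractionation, Gy.
STANDARD_DOSES = (1.8, 2.0)


def classify_regimen(best_dose: float) -> str:
    """Label a best dose as ``hypo``, ``strd`` or ``hyper`` fractionation.

    1.8 and 2 Gy are the clinical standard; fewer, larger fractions
    (> 2 Gy) are hypofractionation, more, smaller ones (< 1.8 Gy)
    hyperfractionation.
    """
    if any(abs(best_dose - s) < 1e-9 for s in STANDARD_DOSES):
        return "strd"
    if best_dose < STANDARD_DOSES[0]:
        return "hyper"
    return "hypo"


def dose_response_correlation(
    doses: Sequence[float], finals: Sequence[float]
) -> float:
    """Pearson correlation between dose per fraction and final volume.

    Negative values mean larger fractions shrink the tumor more (a
    hypo-leaning responder); positive values the opposite.
    """
    doses = np.asarray(doses, dtype=float)
    finals = np.asarray(finals, dtype=float)
    if doses.shape != finals.shape or doses.ndim != 1:
        raise InvalidParameterError("doses and finals must be 1-D and equal length")
    if len(doses) < 3:
        raise UndefinedCorrelationError("need at least 3 points for a correlation")
    if np.ptp(doses) == 0 or np.ptp(finals) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(doses, finals).statistic)


@dataclass(frozen=True)
class RegimenOutcome:
    """Endpoint of one (patient, constant-dose arm) simulation."""

    patient_id: str
    dose: float
    n_fractions: int
    bed: float
    v_a_final: float
    v_t_final: float
    category: str

    def __post_init__(self) -> None:
        if not 0 < self.v_a_final <= self.v_t_final + 1e-12:
            raise InvalidParameterError(
                f"inconsistent endpoint volumes for {self.patient_id} d={self.dose}: "
                f"v_a={self.v_a_final}, v_t={self.v_t_final}"
            )


@dataclass(frozen=True)
class PartialBedOutcome:
    """Minimum-BED early-stop outcome for one (patient, arm).

    ``crossing_day`` is the first day the active volume is observed below
    the threshold, or ``None`` if the course ends without crossing;
    ``bed`` is the cumulative BED of the fractions delivered up to that
    observation (``None`` exactly when there is no crossing).
    """

    patient_id: str
    dose_label: str
    crossing_day: int | None
    bed: float | None

    def __post_init__(self) -> None:
        if (self.crossing_day is None) != (self.bed is None):
            raise InvalidParameterError(
                "BED must be reported exactly when a crossing day exists"
            )


@dataclass(frozen=True)
class DoseGridResult:
    """All outcomes of the constant-dose grid over a cohort."""

    outcomes: tuple[RegimenOutcome, ...]
    doses: tuple[float, ...]

    def patient_ids(self) -> list[str]:
        seen: list[str] = []
        for o in self.outcomes:
            if o.patient_id not in seen:
                seen.append(o.patient_id)
        return seen

    def finals(self, patient_id: str, endpoint: str = "active") -> list[float]:
        """Final volumes of one patient across the dose arms."""
        key = _endpoint_key(endpoint)
        by_dose = {o.dose: getattr(o, key) for o in self.outcomes if o.patient_id == patient_id}
        return [by_dose[d] for d in self.doses]

    def best_dose(self, patient_id: str, endpoint: str = "active") -> float:
        """Arm minimizing the endpoint volume; ties go to the lower dose."""
        finals = self.finals(patient_id, endpoint)
        return min(zip(finals, self.doses))[1]

    def correlation(self, patient_id: str, endpoint: str = "active") -> float:
        return dose_response_correlation(self.doses, self.finals(patient_id, endpoint))

    def summary(self, endpoint: str = "active") -> pd.DataFrame:
        """Mirror of the study's results grid for one endpoint.

        One row per patient: final volume per arm, the dose-response
        correlation, the best dose and its fractionation category.
        """
        rows = []
        for pid in self.patient_ids():
            finals = self.finals(pid, endpoint)
            best = self.best_dose(pid, endpoint)
            row = {"patient": pid}
            row.update({f"d={d:g}": v for d, v in zip(self.doses, finals)})
            row["correlation"] = self.correlation(pid, endpoint)
            row["best_dose"] = best
            row["category"] = classify_regimen(best)
            rows.append(row)
        return pd.DataFrame(rows).set_index("patient")


def _endpoint_key(endpoint: str) -> str:
    if endpoint == "active":
        return "v_a_final"
    if endpoint == "total":
        return "v_t_final"
    raise InvalidParameterError(f"endpoint must be 'active' or 'total', got {endpoint!r}")


def run_dose_grid(
    cohort: Iterable[PatientParameters],
    doses: Sequence[float] = DOSE_GRID,
    target_bed: float = 60.0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> DoseGridResult:
    """Simulate every (patient, constant-dose) arm of the study grid."""
    outcomes = []
    for params in cohort:
        for d in doses:
            sched = constant_schedule(d, target_bed=target_bed)
            res = simulate(params, sched, constants, options)
            outcomes.append(
                RegimenOutcome(
                    patient_id=params.id,
                    dose=float(d),
                    n_fractions=sched.n,
                    bed=sched.bed,
                    v_a_final=res.v_a_final,
                    v_t_final=res.v_t_final,
                    category=classify_regimen(float(d)),
                )
            )
    return DoseGridResult(outcomes=tuple(outcomes), doses=tuple(float(d) for d in doses))


def min_bed_to_threshold(
    params: PatientParameters,
    schedule: FractionationSchedule,
    threshold: float = 20.0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> PartialBedOutcome:
    """Cumulative BED delivered when the active volume first drops below
    ``threshold`` % of the initial volume.

    The course is simulated day by day; on the first day the active
    volume is observed below the threshold, the BED of the fractions
    delivered before that observation (the crossing-causing fraction
    included) is reported.  A course that never crosses is a legal
    outcome reported as ``None``.
    """
    if not 0 < threshold <= 100:
        raise InvalidParameterError(f"threshold must be in (0, 100], got {threshold}")
    res = simulate(params, schedule, constants, options)
    v_a = res.frame["V_a"].to_numpy()
    below = np.nonzero(v_a < threshold)[0]
    if len(below) == 0:
        return PartialBedOutcome(params.id, schedule.label, None, None)
    crossing_day = int(res.frame["day"].iloc[below[0]])
    from .schedule import bed as bed_fn

    partial = bed_fn([dose for day, dose in schedule.fractions if day < crossing_day])
    return PartialBedOutcome(params.id, schedule.label, crossing_day, partial)


def psi(params: PatientParameters, v0: float = 100.0) -> float:
    """Proliferation saturation index: initial volume over carrying capacity.

    A tumor near its carrying capacity (PSI close to 1) proliferates
    slowly; PSI well below 1 leaves room for regrowth between fractions.
    """
    if v0 <= 0:
        raise InvalidParameterError(f"initial volume must be positive, got {v0}")
    return v0 / params.k_hat


@dataclass(frozen=True)
class RampComparison:
    """Endpoint difference between increasing and decreasing dose ramps.

    ``per_patient`` has columns ``v_a_up, v_a_down, abs_diff, rel_diff_pct``;
    ``mean_abs_diff`` is in percentage points of the initial volume and
    ``mean_rel_diff_pct`` is the mean of |up - down| normalized by the
    mean of the two finals, in %.
    """

    per_patient: pd.DataFrame
    mean_abs_diff: float
    mean_rel_diff_pct: float


def ramp_comparison(
    cohort: Iterable[PatientParameters],
    d_min: float = 0.5,
    d_max: float = 4.5,
    delta: float = 0.25,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> RampComparison:
    """Simulate both ramp directions for every patient and summarize.

    Both directions deliver exactly the same dose multiset (hence the
    same BED); only the administration order differs.
    """
    up = ramp_schedule(d_min, d_max, delta, "increasing")
    down = ramp_schedule(d_min, d_max, delta, "decreasing")
    if sorted(up.doses) != sorted(down.doses):
        raise InvalidParameterError("ramp directions must share the same dose multiset")
    rows = []
    for params in cohort:
        v_up = simulate(params, up, constants, options).v_a_final
        v_down = simulate(params, down, constants, options).v_a_final
        diff = abs(v_up - v_down)
        rows.append(
            {
                "patient": params.id,
                "v_a_up": v_up,
                "v_a_down": v_down,
                "abs_diff": diff,
                "rel_diff_pct": 100.0 * diff / ((v_up + v_down) / 2.0),
            }
        )
    frame = pd.DataFrame(rows).set_index("patient")
    return RampComparison(
        per_patient=frame,
        mean_abs_diff=float(frame["abs_diff"].mean()),
        mean_rel_diff_pct=float(frame["rel_diff_pct"].mean()),
    )
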