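"""Macroscale tumor response to fractionated radiotherapy.

The model tracks, day by day, the volume of a tumor normalized to 100% at
the first irradiation:

* the *active* volume ``V_a`` grows by a discrete Gompertz step with rate
  ``rho`` toward the carrying capacity ``k`` and is reduced on irradiation
  days by the linear-quadratic (LQ) surviving fraction;
* the carrying capacity ``k`` — the maximum viable volume the vasculature
  can sustain — is damaged multiplicatively by its own LQ surviving
  fraction (alpha/beta = 3 Gy, kill coefficient ``gamma_v`` < 1);
* oxygenation couples the two: the oxygen-pressure surrogate
  ``PO2 = 100 * (k - V_a) / k`` drives the radiosensitivity ``alpha``
  linearly between ``alpha_min`` and ``alpha_max``, so a damaged
  vasculature (low ``k``) makes the tumor radioresistant;
* cells killed on an irradiation day enter a *necrotic* cohort that is
  cleared with half-time ``T1/2`` (see :func:`clearance_weight` for the
  two clearance laws provided).

The daily update order is: compute PO2 and alpha from the start-of-day
state, grow, kill, append the day's necrotic cohort, damage the carrying
capacity.  Time is an integer day grid; weekends are ordinary no-dose
days on which growth and clearance continue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegeneracyError, InvalidParameterError
from .schedule import FractionationSchedule

__all__ = [
    "ModelConstants",
    "PatientParameters",
    "NecroticCohort",
    "ModelOptions",
    "TumorState",
    "SimulationResult",
    "DEFAULT_CONSTANTS",
    "DEFAULT_OPTIONS",
    "TRAINING_BOUNDS",
    "oxygen_pressure",
    "radiosensitivity",
    "surviving_fraction",
    "clearance_weight",
    "necrotic_volume",
    "step",
    "simulate",
    "initial_state",
]

#: Columns of a trajectory record, in file order.
TRAJECTORY_COLUMNS = (
    "day",
    "dose_Gy",
    "V_a",
    "V_n",
    "V_t",
    "PO2",
    "alpha",
    "SF_t",
    "SF_v",
    "k",
)

#: Training search bounds for the four free patient parameters.
TRAINING_BOUNDS: dict[str, tuple[float, float]] = {
    "rho": (0.01, 0.2),
    "t_half": (2.0, 30.0),
    "k_hat": (100.0, 300.0),
    "gamma_v": (0.0, 1.0),
}


@dataclass(frozen=True)
class ModelConstants:
    """Fixed radiobiological constants.

    ``alpha_min``/``alpha_max`` bound the oxygen-dependent radiosensitivity
    (Gy^-1) so that the tumor surviving fraction at the standard 1.8 Gy
    fraction stays in (0.5, 1).  ``ab_tumor`` and ``ab_vasc`` are the
    alpha/beta ratios (Gy) of tumor and vasculature; ``gamma_tumor`` is the
    tumor kill coefficient, fixed at 1 (the vasculature's ``gamma_v`` is a
    patient parameter).
    """

    alpha_min: float = 0.001
    alpha_max: float = 0.3
    ab_tumor: float = 10.0
    ab_vasc: float = 3.0
    gamma_tumor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_min < self.alpha_max:
            raise InvalidParameterError(
                f"need 0 < alpha_min < alpha_max, got {self.alpha_min}, {self.alpha_max}"
            )
        if self.ab_tumor <= 0 or self.ab_vasc <= 0:
            raise InvalidParameterError("alpha/beta ratios must be positive")
        if self.gamma_tumor != 1.0:
            raise InvalidParameterError("the tumor kill coefficient is fixed at 1")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class PatientParameters:
    """Per-patient free parameters of the model.

    Attributes
    ----------
    id
        Patient label.
    rho
        Gompertz growth rate, day^-1.
    t_half
        Half-time of necrotic (dead-cell) clearance, days.
    k_hat
        Initial carrying capacity, % of the initial tumor volume.
    gamma_v
        Vasculature kill coefficient (dimensionless, < 1: vessels are less
        radiosensitive than tumor cells).
    """

    id: str
    rho: float
    t_half: float
    k_hat: float
    gamma_v: float

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.t_half <= 0 or self.k_hat <= 0:
            raise InvalidParameterError(
                f"rho, t_half and k_hat must be positive ({self})"
            )
        if self.gamma_v < 0:
            raise InvalidParameterError(f"gamma_v must be non-negative ({self})")

    def check_bounds(self, strict: bool = True) -> list[str]:
        """Check the parameters against the training search bounds.

        Returns the list of violation messages; in strict mode a non-empty
        list raises :class:`InvalidParameterError` instead.
        """
        violations = []
        for name, (lo, hi) in TRAINING_BOUNDS.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                violations.append(
                    f"patient {self.id}: {name}={value:g} outside [{lo:g}, {hi:g}]"
                )
        if violations and strict:
            raise InvalidParameterError("; ".join(violations))
        return violations


@dataclass(frozen=True)
class NecroticCohort:
    """Necrotic volume created by one irradiation.

    ``t_i`` is the creation day (the irradiation day index) and ``v0`` the
    volume killed that day, % of the initial tumor volume.
    """

    t_i: int
    v0: float

    def __post_init__(self) -> None:
        if self.t_i < 0:
            raise InvalidParameterError(f"cohort creation day must be >= 0, got {self.t_i}")
        if self.v0 < 0:
            raise InvalidParameterError(f"cohort volume must be >= 0, got {self.v0}")


ClearanceLaw = Literal["compound", "exponential"]


@dataclass(frozen=True)
class ModelOptions:
    """Switches for the under-determined corners of the update rule.

    clearance
        Necrotic clearance law, see :func:`clearance_weight`.  The
        ``"compound"`` default reproduces the reported final total
        volumes; ``"exponential"`` is the plain half-time decay.
    mass_conserving
        If True, the necrotic cohort created on an irradiation day is
        ``G(t) * (1 - SF_t)`` (the kill of the grown volume, so active +
        necrotic mass is conserved within the day); by default it is
        ``V_a(t) * (1 - SF_t)`` (pre-growth volume).
    """

    clearance: ClearanceLaw = "compound"
    mass_conserving: bool = False

    def __post_init__(self) -> None:
        if self.clearance not in ("compound", "exponential"):
            raise InvalidParameterError(
                f"clearance must be 'compound' or 'exponential', got {self.clearance!r}"
            )


DEFAULT_OPTIONS = ModelOptions()


@dataclass(frozen=True)
class TumorState:
    """Instantaneous system state at integer day ``t``.

    Volumes are % of the initial total volume; ``cohorts`` carry the
    necrotic bookkeeping (one entry per past irradiation).
    """

    t: int
    v_a: float
    k: float
    cohorts: tuple[NecroticCohort, ...] = ()

    def __post_init__(self) -> None:
        if self.v_a <= 0:
            raise InvalidParameterError(f"active volume must be positive, got {self.v_a}")
        if self.k <= 0:
            raise InvalidParameterError(f"carrying capacity must be positive, got {self.k}")
        if self.t < 0:
            raise InvalidParameterError(f"day index must be >= 0, got {self.t}")
        if any(c.t_i > self.t for c in self.cohorts):
            raise InvalidParameterError("cohort created after the current day")


def initial_state(params: PatientParameters) -> TumorState:
    """Pre-treatment state: fully active tumor at 100%, capacity at k_hat."""
    return TumorState(t=0, v_a=100.0, k=params.k_hat)


def oxygen_pressure(k: float, v_a: float) -> float:
    """Oxygen partial-pressure surrogate on a 0-100 scale.

    ``PO2 = 100 * (k - v_a) / k``: oxygen availability is set by the spare
    vascular capacity relative to the oxygen-consuming active volume.  The
    value is clamped to [0, 100] (a capacity driven below the active
    volume reads as fully hypoxic).
    """
    if k <= 0:
        raise InvalidParameterError(f"carrying capacity must be positive, got {k}")
    if v_a < 0:
        raise InvalidParameterError(f"active volume must be non-negative, got {v_a}")
    return min(max(100.0 * (k - v_a) / k, 0.0), 100.0)


def radiosensitivity(po2: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Linear oxygen-to-radiosensitivity map, Gy^-1.

    ``alpha = alpha_min + (PO2/100) * (alpha_max - alpha_min)``; fully
    hypoxic tissue is nearly radioresistant (alpha_min), fully oxygenated
    tissue maximally sensitive (alpha_max).
    """
    if not 0.0 <= po2 <= 100.0:
        raise InvalidParameterError(f"PO2 must lie in [0, 100], got {po2}")
    return constants.alpha_min + (po2 / 100.0) * (constants.alpha_max - constants.alpha_min)


def surviving_fraction(alpha: float, gamma: float, d: float, ab: float) -> float:
    """Linear-quadratic surviving fraction of one fraction.

    ``SF = exp(-alpha * gamma * d * (1 + d / ab))``, strictly decreasing
    in each of ``alpha``, ``gamma`` and ``d``, and 1 at zero dose.
    """
    if d < 0:
        raise InvalidParameterError(f"dose must be non-negative, got {d}")
    if alpha <= 0:
        raise InvalidParameterError(f"alpha must be positive, got {alpha}")
    if gamma < 0:
        raise InvalidParameterError(f"gamma must be non-negative, got {gamma}")
    if ab <= 0:
        raise InvalidParameterError(f"alpha/beta must be positive, got {ab}")
    return math.exp(-alpha * gamma * d * (1.0 + d / ab))


def clearance_weight(lag: float, t_half: float, law: ClearanceLaw = "exponential") -> float:
    """Remaining fraction of a necrotic cohort *lag* days after creation.

    ``"exponential"`` is the plain half-time decay ``2^(-lag / t_half)``
    (one half-time after creation exactly half the cohort remains).

    ``"compound"`` re-applies the elapsed-lag factor on every day, i.e.
    the daily update multiplies each cohort by ``2^(-age / t_half)``,
    which compounds to ``2^(-lag (lag + 1) / (2 t_half))``.  Clearance
    therefore accelerates with cohort age; this is the law under which
    the simulator reproduces the reported final total volumes.
    """
    if lag < 0:
        raise InvalidParameterError(f"lag must be non-negative, got {lag}")
    if t_half <= 0:
        raise InvalidParameterError(f"t_half must be positive, got {t_half}")
    if law == "exponential":
        return 2.0 ** (-lag / t_half)
    if law == "compound":
        return 2.0 ** (-lag * (lag + 1.0) / (2.0 * t_half))
    raise InvalidParameterError(f"unknown clearance law {law!r}")


def necrotic_volume(
    state: TumorState, t_half: float, law: ClearanceLaw = "exponential"
) -> float:
    """Total necrotic volume at the state's day, % of initial volume.

    Sums every cohort decayed from its creation day:
    ``sum_i v0_i * w(t - t_i)`` with ``w`` from :func:`clearance_weight`.
    """
    return sum(
        c.v0 * clearance_weight(state.t - c.t_i, t_half, law) for c in state.cohorts
    )


def _day_update(
    state: TumorState,
    dose: float | None,
    params: PatientParameters,
    constants: ModelConstants,
    options: ModelOptions,
) -> tuple[TumorState, dict[str, float]]:
    """One daily step; returns the new state and the day's diagnostics."""
    d = 0.0 if dose is None else float(dose)
    if d < 0:
        raise InvalidParameterError(f"dose must be non-negative, got {d}")

    # oxygenation and radiosensitivity from the start-of-day state
    po2 = oxygen_pressure(state.k, state.v_a)
    alpha = radiosensitivity(po2, constants)
    if d > 0:
        sf_t = surviving_fraction(alpha, constants.gamma_tumor, d, constants.ab_tumor)
        sf_v = surviving_fraction(alpha, params.gamma_v, d, constants.ab_vasc)
    else:
        sf_t = sf_v = 1.0

    # Gompertz growth (factor floored at 0 to guard pathological inputs)
    growth = max(1.0 + params.rho * math.log(state.k / state.v_a), 0.0)
    grown = state.v_a * growth

    new_v_a = grown * sf_t
    new_k = state.k * sf_v
    new_t = state.t + 1
    if new_v_a <= 0 or not math.isfinite(new_v_a):
        raise DegeneracyError(
            f"active volume driven non-positive on day {new_t} "
            f"(v_a={new_v_a!r}, dose={d} Gy)",
            day=new_t,
        )
    if new_k <= 0 or not math.isfinite(new_k):
        raise DegeneracyError(
            f"carrying capacity driven non-positive on day {new_t} "
            f"(k={new_k!r}, dose={d} Gy)",
            day=new_t,
        )

    cohorts = state.cohorts
    if d > 0:
        source = grown if options.mass_conserving else state.v_a
        v0 = source * (1.0 - sf_t)
        if v0 > 0:
            cohorts = cohorts + (NecroticCohort(t_i=state.t, v0=v0),)

    new_state = TumorState(t=new_t, v_a=new_v_a, k=new_k, cohorts=cohorts)
    record = {
        "day": float(state.t),
        "dose_Gy": d,
        "V_a": state.v_a,
        "PO2": po2,
        "alpha": alpha,
        "SF_t": sf_t,
        "SF_v": sf_v,
        "k": state.k,
    }
    return new_state, record


def step(
    state: TumorState,
    dose: float | None,
    params: PatientParameters,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> TumorState:
    """Advance the system by one day.

    ``dose`` is the Gy delivered that day, or ``None``/0 on a rest day
    (surviving fractions are then 1 and no cohort is created).  The
    cohorts are carried forward untouched; their decayed values are
    re-evaluated lazily by :func:`necrotic_volume` at whatever day the
    state is queried.
    """
    new_state, _ = _day_update(state, dose, params, constants, options)
    return new_state


@dataclass(frozen=True)
class SimulationResult:
    """Daily trajectories of one simulated course.

    ``frame`` has one row per day from day 0 through ``t_e`` inclusive
    with columns ``day, dose_Gy, V_a, V_n, V_t, PO2, alpha, SF_t, SF_v, k``
    (volumes in % of the initial total volume).  ``t_e`` is the endpoint
    day: by default the day after the last fraction.
    """

    params: PatientParameters
    frame: pd.DataFrame
    t_e: int
    schedule_label: str = ""

    @property
    def v_a_final(self) -> float:
        """Active volume at the endpoint, % of initial."""
        return float(self.frame["V_a"].iloc[-1])

    @property
    def v_n_final(self) -> float:
        """Necrotic volume at the endpoint, % of initial."""
        return float(self.frame["V_n"].iloc[-1])

    @property
    def v_t_final(self) -> float:
        """Total (active + necrotic) volume at the endpoint, % of initial."""
        return float(self.frame["V_t"].iloc[-1])

    @property
    def po2(self) -> np.ndarray:
        """Daily PO2 series (index aligned with ``frame['day']``)."""
        return self.frame["PO2"].to_numpy()


def simulate(
    params: PatientParameters,
    schedule: FractionationSchedule,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: ModelOptions = DEFAULT_OPTIONS,
    horizon: int | None = None,
) -> SimulationResult:
    """Run the daily-update model over a fractionation schedule.

    The tumor starts fully active at 100% with capacity ``k_hat`` on day 0
    (the first irradiation day).  The course is simulated through the
    endpoint day ``t_e`` — the day after the last fraction, or ``horizon``
    if given (useful for follow-up past the course end).

    Returns a :class:`SimulationResult` with ``t_e + 1`` daily records.
    """
    dose_by_day = schedule.dose_by_day()
    t_e = schedule.last_day + 1 if horizon is None else int(horizon)
    if t_e < 1:
        raise InvalidParameterError(f"horizon must be >= 1, got {t_e}")

    state = initial_state(params)
    rows = []
    for t in range(t_e):
        dose = dose_by_day.get(t, 0.0)
        v_n = necrotic_volume(state, params.t_half, options.clearance)
        new_state, rec = _day_update(state, dose, params, constants, options)
        rec["V_n"] = v_n
        rec["V_t"] = rec["V_a"] + v_n
        rows.append(rec)
        state = new_state

    # endpoint record: no dose applied, diagnostics from the final state
    po2 = oxygen_pressure(state.k, state.v_a)
    v_n = necrotic_volume(state, params.t_half, options.clearance)
    rows.append(
        {
            "day": float(state.t),
            "dose_Gy": 0.0,
            "V_a": state.v_a,
            "V_n": v_n,
            "V_t": state.v_a + v_n,
            "PO2": po2,
            "alpha": radiosensitivity(po2, constants),
            "SF_t": 1.0,
            "SF_v": 1.0,
            "k": state.k,
        }
    )
    frame = pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))
    frame["day"] = frame["day"].astype(int)
    return SimulationResult(
        params=params, frame=frame, t_e=t_e, schedule_label=schedule.label
    )
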