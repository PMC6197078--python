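"""Fractionation calendars and biologically effective dose (BED).

External-beam radiotherapy is delivered as a calendar of dose fractions,
conventionally five per week (Monday-Friday).  Schedules with different
doses per fraction are made comparable by holding the biologically
effective dose fixed,

    BED = sum_i d_i * (1 + d_i / (alpha/beta)),

with alpha/beta = 10 Gy for tumor tissue.  This module builds the two
schedule families studied by the simulator: constant dose per fraction
(the fraction count chosen so the BED is as close as possible to a
target, 60 Gy by default) and linear dose ramps at a fixed dose multiset
(increasing or decreasing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InvalidParameterError

#: alpha/beta ratio used for BED bookkeeping of tumor tissue, Gy.
DEFAULT_AB = 10.0

#: Dose-per-fraction bounds for constant-dose courses, Gy.
CONSTANT_DOSE_RANGE = (0.5, 3.0)

#: Dose-per-fraction bounds for ramped (non-constant) courses, Gy.
RAMP_DOSE_RANGE = (0.5, 4.5)


def bed(doses: Iterable[float], ab: float = DEFAULT_AB) -> float:
    """Biologically effective dose of a list of fraction doses.

    Parameters
    ----------
    doses
        Nominal dose of each fraction, Gy.  May be empty.
    ab
        alpha/beta ratio of the tissue, Gy.

    Returns
    -------
    float
        ``sum(d * (1 + d / ab))`` in Gy.  Additive over concatenation and
        invariant under permutation of the fractions.
    """
    if ab <= 0:
        raise InvalidParameterError(f"alpha/beta ratio must be positive, got {ab}")
    total = 0.0
    for d in doses:
        if d < 0:
            raise InvalidParameterError(f"fraction dose must be non-negative, got {d}")
        total += d * (1.0 + d / ab)
    return total


def _weekday_calendar(n: int, per_week: int) -> list[int]:
    """Day indices for *n* fractions, *per_week* consecutive days per 7-day week.

    Day 0 is a Monday; with the default five fractions per week the gaps
    are one day within a week and three days across a weekend.
    """
    if not 1 <= per_week <= 7:
        raise InvalidParameterError(f"per_week must be in 1..7, got {per_week}")
    return [(i // per_week) * 7 + (i % per_week) for i in range(n)]


@dataclass(frozen=True)
class FractionationSchedule:
    """An ordered irradiation calendar.

    Attributes
    ----------
    fractions
        Ordered ``(day, dose)`` pairs; day indices are integers counted
        from the first irradiation (day 0), doses in Gy.
    label
        Human-readable tag, e.g. ``"const d=1.8"``.
    """

    fractions: tuple[tuple[int, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.fractions:
            raise InvalidParameterError("schedule must contain at least one fraction")
        days = [day for day, _ in self.fractions]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidParameterError("fraction days must be strictly increasing")
        if any(day < 0 for day in days):
            raise InvalidParameterError("fraction days must be non-negative")
        if any(dose <= 0 for _, dose in self.fractions):
            raise InvalidParameterError("all fraction doses must be positive")
        # no more than 5 fractions in any 7 consecutive days
        for i, start in enumerate(days):
            in_window = sum(1 for d in days[i:] if d < start + 7)
            if in_window > 5:
                raise InvalidParameterError(
                    f"more than 5 fractions in the 7-day window starting day {start}"
                )

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(day for day, _ in self.fractions)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(dose for _, dose in self.fractions)

    @property
    def n(self) -> int:
        """Fraction count."""
        return len(self.fractions)

    @property
    def total_dose(self) -> float:
        """Total physical dose, Gy."""
        return sum(self.doses)

    @property
    def bed(self) -> float:
        """Realized BED at the tumor alpha/beta ratio (10 Gy)."""
        return bed(self.doses, DEFAULT_AB)

    @property
    def last_day(self) -> int:
        return self.fractions[-1][0]

    def bed_at(self, ab: float) -> float:
        """Realized BED at an arbitrary alpha/beta ratio."""
        return bed(self.doses, ab)

    def dose_on(self, day: int) -> float:
        """Dose delivered on *day* (0 if it is a rest day)."""
        for d, dose in self.fractions:
            if d == day:
                return dose
        return 0.0

    def dose_by_day(self) -> dict[int, float]:
        return dict(self.fractions)


def constant_schedule(
    d: float,
    target_bed: float = 60.0,
    ab: float = DEFAULT_AB,
    per_week: int = 5,
    strict: bool = True,
) -> FractionationSchedule:
    """Constant dose-per-fraction course with BED closest to *target_bed*.

    The fraction count N minimizes ``|N * d * (1 + d/ab) - target_bed|``;
    ties are broken toward fewer fractions.  Fractions are placed on
    consecutive weekdays starting from day 0 (a Monday).

    With the defaults, ``d = 1.8`` yields the canonical 28-fraction course
    (BED 59.47 Gy), ``d = 3`` yields 15 fractions and ``d = 1`` yields 55.

    In strict mode the dose must lie in the 0.5-3 Gy window used for
    constant-dose courses; outside it a warning is emitted instead when
    ``strict=False``.
    """
    if d <= 0:
        raise InvalidParameterError(f"dose per fraction must be positive, got {d}")
    lo, hi = CONSTANT_DOSE_RANGE
    if not lo <= d <= hi:
        msg = f"dose {d} Gy outside the constant-dose window [{lo}, {hi}] Gy"
        if strict:
            raise InvalidParameterError(msg)
        warnings.warn(msg, stacklevel=2)
    if target_bed <= 0:
        raise InvalidParameterError(f"target BED must be positive, got {target_bed}")
    per_fraction = d * (1.0 + d / ab)
    floor_n = max(int(target_bed // per_fraction), 1)
    # nearest-BED rounding, ties -> fewer fractions
    n = min(
        (floor_n, floor_n + 1),
        key=lambda m: (abs(m * per_fraction - target_bed), m),
    )
    days = _weekday_calendar(n, per_week)
    return FractionationSchedule(
        fractions=tuple((day, float(d)) for day in days),
        label=f"const d={d:g}",
    )


def ramp_schedule(
    d_min: float = 0.5,
    d_max: float = 4.5,
    delta: float = 0.25,
    direction: str = "increasing",
    per_week: int = 5,
) -> FractionationSchedule:
    """Linearly ramped course: doses d_min, d_min+delta, ..., d_max.

    The defaults give 17 fractions with mean dose 2.5 Gy and a dose
    increment of 0.25 Gy between consecutive fractions.  ``direction=
    "decreasing"`` reverses the order; both directions share the same dose
    multiset and therefore the same BED.
    """
    if direction not in ("increasing", "decreasing"):
        raise InvalidParameterError(
            f"direction must be 'increasing' or 'decreasing', got {direction!r}"
        )
    if d_min <= 0 or d_max < d_min or delta <= 0:
        raise InvalidParameterError(
            f"inconsistent ramp bounds: d_min={d_min}, d_max={d_max}, delta={delta}"
        )
    steps = (d_max - d_min) / delta
    if abs(steps - round(steps)) > 1e-9:
        raise InvalidParameterError(
            f"(d_max - d_min) = {d_max - d_min} is not a multiple of delta = {delta}"
        )
    n = int(round(steps)) + 1
    doses = [d_min + i * delta for i in range(n)]
    if direction == "decreasing":
        doses.reverse()
    days = _weekday_calendar(n, per_week)
    arrow = "up" if direction == "increasing" else "down"
    return FractionationSchedule(
        fractions=tuple((day, float(dose)) for day, dose in zip(days, doses)),
        label=f"ramp {arrow} {d_min:g}-{d_max:g}",
    )
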