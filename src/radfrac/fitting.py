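"""Monte Carlo parameter estimation from tumor-volume time series.

The four free parameters (rho, T1/2, k_hat, gamma_v) are estimated by
plain uniform random search inside the published training bounds: draw
parameter vectors, simulate the measured schedule, score each draw by
the root-mean-square error between simulated and observed total volume
at the observation days, and keep the best.  The fitter reports the
top-k vectors, not only the argmin, because distinct (T1/2, gamma_v)
pairs can produce near-identical volume fits — the ranking makes that
practical non-identifiability visible instead of hiding it.

Simulation of the draws is vectorized over the sample axis; the batch
path is numerically identical (to machine precision) to the scalar
:func:`radfrac.model.simulate` and is cross-checked against it in the
test suite.

A synthetic-series generator is included for parameter-recovery
exercises (the clinical volume series behind the published cohort are
not public).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, UndefinedCorrelationError
from .model import (
    DEFAULT_CONSTANTS,
    DEFAULT_OPTIONS,
    TRAINING_BOUNDS,
    ModelConstants,
    ModelOptions,
    PatientParameters,
    simulate,
)
from .schedule import FractionationSchedule

logger = logging.getLogger("radfrac")

__all__ = [
    "ParameterBounds",
    "VolumeSeries",
    "FitResult",
    "fit_parameters",
    "generate_series",
    "correlate_oxygenation",
]

_PARAM_NAMES = ("rho", "t_half", "k_hat", "gamma_v")


@dataclass(frozen=True)
class ParameterBounds:
    """Uniform search box for the four free parameters.

    Defaults are the published training intervals: rho in [0.01, 0.2]
    /day, T1/2 in [2, 30] days, k_hat in [100, 300] % and gamma_v in
    [0, 1].  A bound may be collapsed (lo == hi) to pin a parameter.
    """

    rho: tuple[float, float] = TRAINING_BOUNDS["rho"]
    t_half: tuple[float, float] = TRAINING_BOUNDS["t_half"]
    k_hat: tuple[float, float] = TRAINING_BOUNDS["k_hat"]
    gamma_v: tuple[float, float] = TRAINING_BOUNDS["gamma_v"]

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidParameterError(f"{name}: lower bound {lo} > upper {hi}")
        if self.rho[0] <= 0 or self.t_half[0] <= 0 or self.k_hat[0] <= 0:
            raise InvalidParameterError("rho, t_half, k_hat lower bounds must be positive")
        if self.gamma_v[0] < 0:
            raise InvalidParameterError("gamma_v lower bound must be non-negative")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([getattr(self, n)[0] for n in _PARAM_NAMES])
        hi = np.array([getattr(self, n)[1] for n in _PARAM_NAMES])
        return lo, hi


@dataclass(frozen=True)
class VolumeSeries:
    """Observed total tumor volume under a known schedule.

    ``days`` are non-negative, strictly increasing integers; ``volumes``
    are total volumes in % of the initial volume (if day 0 is observed
    it must read 100, the normalization reference).
    """

    days: tuple[int, ...]
    volumes: tuple[float, ...]
    schedule: FractionationSchedule

    def __post_init__(self) -> None:
        if len(self.days) != len(self.volumes):
            raise InvalidParameterError("days and volumes must have equal length")
        if len(self.days) == 0:
            raise InvalidParameterError("series must contain at least one observation")
        if any(d < 0 for d in self.days):
            raise InvalidParameterError("observation days must be non-negative")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise InvalidParameterError("observation days must be strictly increasing")
        if any(v <= 0 for v in self.volumes):
            raise InvalidParameterError("volumes must be positive")
        if self.days[0] == 0 and abs(self.volumes[0] - 100.0) > 1e-9:
            raise InvalidParameterError(
                f"day-0 volume must be 100 (the normalization), got {self.volumes[0]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "V_t": self.volumes})


def _simulate_vt_batch(
    theta: np.ndarray,
    schedule: FractionationSchedule,
    obs_days: Sequence[int],
    constants: ModelConstants,
    options: ModelOptions,
) -> np.ndarray:
    """Total-volume trajectories for a batch of parameter vectors.

    ``theta`` is (S, 4) with columns rho, t_half, k_hat, gamma_v; the
    return value is (S, len(obs_days)).  Implements exactly the daily
    update of :mod:`radfrac.model`, vectorized over the sample axis.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    rho, t_half, k_hat, gamma_v = theta.T
    horizon = max(int(max(obs_days)), schedule.last_day + 1)
    dose_by_day = schedule.dose_by_day()

    S = theta.shape[0]
    v_a = np.full(S, 100.0)
    k = k_hat.copy()
    va_traj = np.empty((S, horizon + 1))
    va_traj[:, 0] = v_a
    kill_days: list[int] = []
    kills: list[np.ndarray] = []

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for t in range(horizon):
            d = dose_by_day.get(t, 0.0)
            po2 = np.clip(100.0 * (k - v_a) / k, 0.0, 100.0)
            alpha = constants.alpha_min + (po2 / 100.0) * (
                constants.alpha_max - constants.alpha_min
            )
            if d > 0:
                sf_t = np.exp(-alpha * constants.gamma_tumor * d * (1.0 + d / constants.ab_tumor))
                sf_v = np.exp(-alpha * gamma_v * d * (1.0 + d / constants.ab_vasc))
            else:
                sf_t = sf_v = 1.0
            grown = v_a * np.maximum(1.0 + rho * np.log(k / v_a), 0.0)
            if d > 0:
                source = grown if options.mass_conserving else v_a
                kill_days.append(t)
                kills.append(source * (1.0 - sf_t))
            v_a = grown * sf_t
            k = k * sf_v
            va_traj[:, t + 1] = v_a

    obs = np.asarray(obs_days, dtype=int)
    v_t = va_traj[:, obs].copy()
    if kills:
        kill_matrix = np.stack(kills, axis=1)  # (S, n_fractions)
        kd = np.asarray(kill_days)
        for j, day in enumerate(obs):
            lag = day - kd  # (n_fractions,)
            active = lag > 0
            if not active.any():
                continue
            L = lag[active].astype(float)
            if options.clearance == "compound":
                expo = L * (L + 1.0) / 2.0
            else:
                expo = L
            w = 2.0 ** (-expo[None, :] / t_half[:, None])
            v_t[:, j] += (kill_matrix[:, active] * w).sum(axis=1)
    return v_t


@dataclass(frozen=True)
class FitResult:
    """Best draw of a Monte Carlo search plus the surrounding ranking."""

    best: PatientParameters
    loss: float
    top: pd.DataFrame
    n_samples: int
    n_failed: int


def fit_parameters(
    series: VolumeSeries,
    bounds: ParameterBounds = ParameterBounds(),
    n_samples: int = 50_000,
    seed: int | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: ModelOptions = DEFAULT_OPTIONS,
    top_k: int = 10,
    chunk_size: int = 100_000,
    patient_id: str = "fit",
) -> FitResult:
    """Uniform random search for the parameter vector minimizing RMSE.

    Draws ``n_samples`` vectors uniformly inside ``bounds`` (deterministic
    given ``seed``), simulates each under the series' schedule, and ranks
    them by root-mean-square error between simulated and observed total
    volume at the observation days.  Draws whose simulation degenerates
    numerically are skipped with a logged warning, not a failure.
    """
    if n_samples < 1:
        raise InvalidParameterError(f"n_samples must be >= 1, got {n_samples}")
    if len(series.days) < 2:
        raise InvalidParameterError("need at least 2 observations to fit")
    lo, hi = bounds.as_arrays()
    rng = np.random.default_rng(seed)
    target = np.asarray(series.volumes, dtype=float)

    best_rows: list[np.ndarray] = []
    best_losses: list[np.ndarray] = []
    n_failed = 0
    for start in range(0, n_samples, chunk_size):
        m = min(chunk_size, n_samples - start)
        theta = rng.uniform(lo, hi, size=(m, 4))
        v_t = _simulate_vt_batch(theta, series.schedule, series.days, constants, options)
        loss = np.sqrt(np.mean((v_t - target[None, :]) ** 2, axis=1))
        bad = ~np.isfinite(loss)
        if bad.any():
            n_failed += int(bad.sum())
            loss = np.where(bad, np.inf, loss)
        keep = np.argsort(loss, kind="stable")[: max(top_k, 1)]
        best_rows.append(theta[keep])
        best_losses.append(loss[keep])
    if n_failed:
        logger.warning("skipped %d unsimulatable parameter draws", n_failed)

    theta_top = np.concatenate(best_rows)
    loss_top = np.concatenate(best_losses)
    order = np.argsort(loss_top, kind="stable")[: max(top_k, 1)]
    theta_top, loss_top = theta_top[order], loss_top[order]
    if not np.isfinite(loss_top[0]):
        raise InvalidParameterError("every parameter draw failed to simulate")

    top = pd.DataFrame(theta_top, columns=list(_PARAM_NAMES))
    top["loss"] = loss_top
    best = PatientParameters(
        id=patient_id,
        rho=float(theta_top[0, 0]),
        t_half=float(theta_top[0, 1]),
        k_hat=float(theta_top[0, 2]),
        gamma_v=float(theta_top[0, 3]),
    )
    return FitResult(
        best=best,
        loss=float(loss_top[0]),
        top=top,
        n_samples=n_samples,
        n_failed=n_failed,
    )


def generate_series(
    params: PatientParameters,
    schedule: FractionationSchedule,
    obs_days: Sequence[int],
    noise_sd: float = 0.0,
    seed: int | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    options: ModelOptions = DEFAULT_OPTIONS,
) -> VolumeSeries:
    """Synthetic total-volume series from a known parameter vector.

    Observations are the simulated ``V_t`` at ``obs_days``; optional
    multiplicative Gaussian noise with standard deviation ``noise_sd``
    (in % of the value) is applied, clipped to stay positive.  Tumor
    volumes span orders of magnitude over a course, which is why the
    noise is multiplicative rather than additive.  A day-0 observation
    is left exactly at 100, the normalization reference.
    """
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    obs_days = [int(d) for d in obs_days]
    if any(d < 0 for d in obs_days):
        raise InvalidParameterError("observation days must be non-negative")
    horizon = max(max(obs_days), schedule.last_day + 1)
    res = simulate(params, schedule, constants, options, horizon=horizon)
    v_t = res.frame.set_index("day")["V_t"]
    values = np.array([v_t.loc[d] for d in obs_days], dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        factor = 1.0 + rng.normal(0.0, noise_sd / 100.0, size=len(values))
        factor = np.clip(factor, 1e-6, None)
        values = values * factor
        values[np.asarray(obs_days) == 0] = 100.0
    return VolumeSeries(
        days=tuple(obs_days), volumes=tuple(float(v) for v in values), schedule=schedule
    )


def correlate_oxygenation(
    po2_series: Sequence[float], index_series: Sequence[float]
) -> float:
    """Pearson correlation between model PO2 and a Doppler-derived index.

    Vascularization/flow indices (VI, FI, VFI) relate to oxygen
    availability without being oxygen pressures; their correlation with
    the model's PO2 trajectory measures how well the simulated
    oxygenation dynamics track the imaging surrogate.  The index series
    itself is user-supplied — no image processing happens here.
    """
    x = np.asarray(po2_series, dtype=float)
    y = np.asarray(index_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("series must be 1-D, aligned and equal length")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 aligned points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant series")
    return float(stats.pearsonr(x, y).statistic)
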