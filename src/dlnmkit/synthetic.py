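"""Synthetic daily weather and case-count generator.

Emulates the structure of an ~11-year single-city daily surveillance
series: sparse overdispersed counts (on the order of 0.2 cases/day),
seasonal day-of-week-structured baseline rates, and nine meteorological
exposures with annual cycles and day-to-day autocorrelation whose moments
are calibrated to the descriptive statistics of the Shenzhen study window
(e.g. mean temperature 23.25 +/- 5.50 degC).  A configurable, known
exposure-lag-response surface is injected so parameter recovery can be
checked end to end; real data of course carry no such known truth, so
passing recovery tests demonstrates correctness of the estimation
machinery, not validity of any particular epidemiological finding.

Weather model per factor:

    x_t = annual_mean + A * cos(2*pi*(t - phase_day)/365.25) + e_t,
    e_t = ar * e_{t-1} + N(0, noise_sd^2),

clipped to physical bounds and rounded to the recording precision.
Counts:

    log mu_t = log(mean_daily_count) + seasonal + trend + dow
               + sum_{l=0..maxlag} f(x_{t-l}, l),
    Y_t ~ Poisson(mu_t)                      (dispersion = 1)
    Y_t ~ NB(size k_t = mu_t/(phi-1))        (dispersion = phi > 1)

the NB size is chosen per day so Var(Y_t) = phi * mu_t exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FactorSpec",
    "TrueSurface",
    "BaselineSpec",
    "simulate_weather",
    "simulate_counts",
    "simulate_dataset",
    "FACTOR_PRESETS",
    "CALIBRATION_TARGETS",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class FactorSpec:
    """Generative description of one meteorological factor.

    ``soft_clip_width`` controls how values are confined to ``bounds``:
    zero applies a hard clip, which concentrates an atom of probability at
    a bound (appropriate where the recorded mode genuinely sits at a bound,
    e.g. full cloud cover or zero sunshine); a positive width compresses
    the tails smoothly into the bounds instead, so the most frequent
    recorded value stays interior, as it is for temperature and the other
    continuously distributed factors.
    """

    name: str
    annual_mean: float
    seasonal_amplitude: float
    phase_day: int
    ar_coefficient: float
    noise_sd: float
    bounds: tuple[float, float]
    precision: float = 0.1
    soft_clip_width: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must satisfy lo < hi")
        if self.soft_clip_width < 0:
            raise ValueError("soft_clip_width must be >= 0")


@dataclass(frozen=True)
class TrueSurface:
    """Known exposure-lag-response surface f(x, lag) on the log-RR scale.

    Quadratic in exposure around the reference ``x_ref`` (where f == 0 for
    every lag) with exponential decay over lag:

        f(x, l) = gamma * ((x - x_ref)/scale)^2 * exp(-l / tau)

    ``gamma = 0`` gives the null surface.  Smooth within the span of a
    low-df cross-basis, so recovery is achievable by design.
    """

    x_ref: float
    gamma: float
    scale: float
    tau: float = 3.0
    maxlag: int = 14

    def log_rr(self, x, lag) -> np.ndarray:
        xv = np.asarray(x, float)
        lv = np.asarray(lag, float)
        out = self.gamma * ((xv - self.x_ref) / self.scale) ** 2 * np.exp(-lv / self.tau)
        if not np.all(np.isfinite(out)):
            raise ValueError("surface evaluates to non-finite values")
        return out

    def cumulative_log_rr(self, x, upto: int | None = None) -> np.ndarray:
        upto = self.maxlag if upto is None else upto
        lags = np.arange(upto + 1)
        xv = np.atleast_1d(np.asarray(x, float))
        return self.log_rr(xv[:, None], lags[None, :]).sum(axis=1)

    @classmethod
    def null(cls, x_ref: float = 0.0) -> "TrueSurface":
        return cls(x_ref=x_ref, gamma=0.0, scale=1.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline (exposure-free) structure of the daily incidence rate."""

    mean_daily_count: float = 863.0 / 4078.0
    seasonal_log_amplitude: float = 0.15
    seasonal_phase_day: int = 20
    trend_log_slope_per_year: float = 0.01
    dow_log_effects: tuple[float, ...] = (0.0, 0.02, 0.01, 0.0, -0.01, -0.05, -0.08)
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_daily_count <= 0:
            raise ValueError("mean_daily_count must be positive")
        if len(self.dow_log_effects) != 7:
            raise ValueError("dow_log_effects must have 7 entries (Mon..Sun)")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_weather(n_days: int, spec: FactorSpec, seed: int) -> np.ndarray:
    """Seasonal AR(1) weather series, clipped and rounded per the spec."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    seasonal = spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (t - spec.phase_day) / DAYS_PER_YEAR
    )
    e = np.empty(n_days)
    stat_sd = spec.noise_sd / math.sqrt(1.0 - spec.ar_coefficient**2)
    e[0] = rng.normal(0.0, stat_sd)
    shocks = rng.normal(0.0, spec.noise_sd, size=n_days)
    for i in range(1, n_days):
        e[i] = spec.ar_coefficient * e[i - 1] + shocks[i]
    x = spec.annual_mean + seasonal + e
    lo, hi = spec.bounds
    w = spec.soft_clip_width
    if w > 0:
        # smooth compression into (lo, hi): asymptotes to the bounds with
        # no probability atom at either one
        x = hi - w * np.logaddexp(0.0, (hi - x) / w)
        x = lo + w * np.logaddexp(0.0, (x - lo) / w)
    x = np.clip(x, lo, hi)
    return np.round(x / spec.precision) * spec.precision


def expected_log_mean(
    exposure: Mapping[str, np.ndarray] | np.ndarray,
    surface: Mapping[str, TrueSurface] | TrueSurface | None,
    baseline: BaselineSpec,
    weekday: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic log mean of the count process (the generator's truth).

    For the first ``maxlag`` days the lag sum runs over the available
    history only; those burn-in days are flagged by :func:`simulate_counts`
    and excluded from model fitting downstream.
    """
    if isinstance(exposure, np.ndarray):
        exposure = {"x": exposure}
        if surface is not None and not isinstance(surface, Mapping):
            surface = {"x": surface}
    elif isinstance(surface, TrueSurface):
        raise ValueError("with named exposures, surface must map factor -> surface")
    n = len(next(iter(exposure.values())))
    t = np.arange(n)
    log_mu = (
        math.log(baseline.mean_daily_count)
        + baseline.seasonal_log_amplitude
        * np.cos(2.0 * np.pi * (t - baseline.seasonal_phase_day) / DAYS_PER_YEAR)
        + baseline.trend_log_slope_per_year * (t / DAYS_PER_YEAR)
    )
    if weekday is None:
        weekday = t % 7
    log_mu = log_mu + np.asarray(baseline.dow_log_effects)[weekday]
    if surface:
        for name, surf in surface.items():
            x = np.asarray(exposure[name], float)
            L = surf.maxlag
            for lag in range(L + 1):
                contrib = surf.log_rr(x[: n - lag], lag)
                log_mu[lag:] = log_mu[lag:] + contrib
    if not np.all(np.isfinite(log_mu)):
        raise ValueError("non-finite log mean; check surface/baseline parameters")
    return log_mu


def simulate_counts(
    exposure: Mapping[str, np.ndarray] | np.ndarray,
    surface: Mapping[str, TrueSurface] | TrueSurface | None,
    baseline: BaselineSpec,
    seed: int,
    weekday: np.ndarray | None = None,
    return_mean: bool = False,
):
    """Draw daily counts given exposures, a true surface and a baseline.

    Returns the count vector (and the daily mean when ``return_mean``);
    the first ``maxlag`` days are burn-in — their lag sums are truncated to
    the available history.
    """
    log_mu = expected_log_mean(exposure, surface, baseline, weekday=weekday)
    mu = np.exp(log_mu)
    rng = np.random.default_rng(seed)
    phi = baseline.dispersion
    if phi == 1.0:
        y = rng.poisson(mu)
    else:
        k = mu / (phi - 1.0)
        y = rng.negative_binomial(k, k / (k + mu))
    if return_mean:
        return y, mu
    return y


# ---------------------------------------------------------------------------
# Factor presets calibrated to the Shenzhen 2009-2020 descriptive moments
# ---------------------------------------------------------------------------

FACTOR_PRESETS: dict[str, FactorSpec] = {
    "mean_temperature": FactorSpec(
        name="mean_temperature", annual_mean=23.4, seasonal_amplitude=6.3,
        phase_day=196, ar_coefficient=0.85, noise_sd=1.65,
        bounds=(3.5, 33.0), precision=0.1, soft_clip_width=1.0,
    ),
    "relative_humidity": FactorSpec(
        name="relative_humidity", annual_mean=75.6, seasonal_amplitude=6.0,
        phase_day=170, ar_coefficient=0.75, noise_sd=8.3,
        bounds=(19.0, 100.0), precision=1.0, soft_clip_width=3.0,
    ),
    "wind_speed": FactorSpec(
        name="wind_speed", annual_mean=20.6, seasonal_amplitude=2.5,
        phase_day=335, ar_coefficient=0.6, noise_sd=6.3,
        bounds=(3.0, 67.0), precision=1.0, soft_clip_width=2.0,
    ),
    "mean_air_pressure": FactorSpec(
        name="mean_air_pressure", annual_mean=1005.4, seasonal_amplitude=7.2,
        phase_day=10, ar_coefficient=0.8, noise_sd=2.5,
        bounds=(983.1, 1027.3), precision=0.1, soft_clip_width=2.0,
    ),
    "visibility": FactorSpec(
        name="visibility", annual_mean=18.1, seasonal_amplitude=3.5,
        phase_day=300, ar_coefficient=0.7, noise_sd=5.35,
        bounds=(1.8, 39.3), precision=0.1, soft_clip_width=2.0,
    ),
    "total_cloud_cover": FactorSpec(
        name="total_cloud_cover", annual_mean=66.0, seasonal_amplitude=13.0,
        phase_day=170, ar_coefficient=0.6, noise_sd=21.0,
        bounds=(0.0, 100.0), precision=1.0,
    ),
    "sunshine_duration": FactorSpec(
        name="sunshine_duration", annual_mean=5.0, seasonal_amplitude=1.6,
        phase_day=230, ar_coefficient=0.5, noise_sd=3.6,
        bounds=(0.0, 12.5), precision=0.1,
    ),
    "daily_evaporation": FactorSpec(
        name="daily_evaporation", annual_mean=3.3, seasonal_amplitude=1.0,
        phase_day=196, ar_coefficient=0.6, noise_sd=1.15,
        bounds=(0.0, 12.0), precision=0.1, soft_clip_width=0.8,
    ),
    "solar_radiation": FactorSpec(
        name="solar_radiation", annual_mean=146.0, seasonal_amplitude=47.0,
        phase_day=170, ar_coefficient=0.6, noise_sd=48.0,
        bounds=(15.0, 335.0), precision=0.1, soft_clip_width=20.0,
    ),
}

# Published moments each preset targets, with per-factor tolerances used by
# the calibration checks (mean_tol ~ 0.1 SD, sd_tol ~ 0.2 SD, loosened where
# boundary clipping makes moments sensitive).
CALIBRATION_TARGETS: dict[str, dict[str, float]] = {
    "mean_temperature": {"mean": 23.25, "sd": 5.50, "mean_tol": 0.5, "sd_tol": 1.0},
    "relative_humidity": {"mean": 74.71, "sd": 12.99, "mean_tol": 1.3, "sd_tol": 2.6},
    "wind_speed": {"mean": 20.61, "sd": 8.04, "mean_tol": 0.8, "sd_tol": 1.6},
    "mean_air_pressure": {"mean": 1005.42, "sd": 6.43, "mean_tol": 0.7, "sd_tol": 1.3},
    "visibility": {"mean": 18.09, "sd": 7.82, "mean_tol": 0.8, "sd_tol": 1.6},
    "total_cloud_cover": {"mean": 64.59, "sd": 25.05, "mean_tol": 2.5, "sd_tol": 5.0},
    "sunshine_duration": {"mean": 5.23, "sd": 3.78, "mean_tol": 0.6, "sd_tol": 1.0},
    "daily_evaporation": {"mean": 3.30, "sd": 1.62, "mean_tol": 0.35, "sd_tol": 0.7},
    "solar_radiation": {"mean": 144.45, "sd": 69.18, "mean_tol": 7.0, "sd_tol": 14.0},
}


def simulate_dataset(
    n_days: int = 4078,
    factors: Sequence[str] | None = None,
    surfaces: Mapping[str, TrueSurface] | None = None,
    baseline: BaselineSpec | None = None,
    seed: int = 0,
    start_date: str = "2009-01-01",
) -> tuple[pd.DataFrame, dict]:
    """Full synthetic study table plus a truth sidecar.

    Returns a DataFrame with columns ``date``, ``count`` and one column per
    factor, and a dict recording every generative parameter (writable as a
    YAML sidecar via :func:`write_truth`).  Weather and counts use
    independent child streams spawned from ``seed``.
    """
    if factors is None:
        factors = list(FACTOR_PRESETS)
    baseline = baseline or BaselineSpec()
    surfaces = dict(surfaces or {})
    unknown = set(surfaces) - set(factors)
    if unknown:
        raise ValueError(f"surfaces refer to absent factors: {sorted(unknown)}")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(factors) + 1)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    data: dict[str, np.ndarray] = {}
    for child, name in zip(children[:-1], factors):
        spec = FACTOR_PRESETS[name]
        data[name] = simulate_weather(n_days, spec, seed=child)
    counts = simulate_counts(
        data,
        surfaces,
        baseline,
        seed=children[-1],
        weekday=dates.weekday.to_numpy(),
    )
    df = pd.DataFrame({"date": dates, "count": counts, **data})
    truth = {
        "seed": int(seed),
        "n_days": int(n_days),
        "start_date": str(start_date),
        "baseline": baseline.to_dict(),
        "factors": {name: asdict(FACTOR_PRESETS[name]) for name in factors},
        "surfaces": {name: s.to_dict() for name, s in surfaces.items()},
    }
    return df, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
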