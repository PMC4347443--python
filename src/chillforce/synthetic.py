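"""Synthetic weather, treatment schedules and budburst observations.

The generators emulate the structure of a greenhouse/ambient dormancy
trial and of multi-year weather-station records, so that every pipeline
stage can be exercised end-to-end with no external data:

* ambient hourly temperature = annual sinusoid + diurnal sinusoid +
  seeded AR(1) noise;
* treatment series follow a weekly environment pattern (greenhouse held
  at a minimum setpoint, growth chamber at a fixed setpoint, ambient or
  cold-site exposure), after the standard trial regimes;
* per-seedling budburst observations are drawn from a known possibility
  line with lognormal seedling-to-seedling variation in the forcing
  requirement, reported only on periodic check dates;
* station gradients span mild-maritime to cold-montane winters with a
  shared monthly warming scenario.

All generators are deterministic for a fixed integer seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .accumulation import TemperatureSeries, _as_datetime, accumulate_units
from .curves import EffectivenessCurve
from .possibility import (
    BudburstObservationSet,
    PossibilityLine,
    SeedlingRecord,
    required_forcing,
)
from .projection import MonthlyDeltas, StationRecord

__all__ = [
    "AmbientClimate",
    "TreatmentSchedule",
    "olympia_ambient",
    "standard_schedules",
    "generate_ambient_series",
    "generate_treatment_series",
    "simulate_budburst_observations",
    "generate_station_gradient",
]

ENVIRONMENT_TAGS = ("greenhouse", "ambient", "chamber", "cold")


@dataclass(frozen=True)
class AmbientClimate:
    """Parameters of the synthetic outdoor temperature process.

    ``annual_mean`` (degC) with a seasonal cosine of amplitude
    ``seasonal_amp`` whose minimum falls on calendar day ``coldest_doy``,
    a diurnal cosine of amplitude ``diurnal_amp`` peaking at
    ``warmest_hour``, and stationary AR(1) noise with marginal standard
    deviation ``noise_sd`` and lag-1 autocorrelation ``noise_ar1``.
    """

    annual_mean: float = 9.14
    seasonal_amp: float = 7.0
    diurnal_amp: float = 3.0
    noise_sd: float = 2.5
    noise_ar1: float = 0.85
    coldest_doy: float = 10.0
    warmest_hour: float = 15.0

    def __post_init__(self) -> None:
        if self.seasonal_amp < 0 or self.diurnal_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise sd must be >= 0")
        if not abs(self.noise_ar1) < 1:
            raise ValueError("|noise_ar1| must be < 1 for a stationary process")


def olympia_ambient() -> AmbientClimate:
    """Mild maritime Pacific Northwest climate.

    Calibrated so the deterministic component averages ~4.0 degC over
    November 1 - March 31, matching the lath-house winters the trial
    design assumes.
    """
    return AmbientClimate()


@dataclass(frozen=True)
class TreatmentSchedule:
    """Weekly environment pattern for one temperature treatment.

    ``pattern`` assigns one environment tag per weekday (index 0 =
    Monday): ``greenhouse`` holds ambient up to a minimum setpoint,
    ``chamber`` is a fixed setpoint, ``ambient`` is the outdoor draw and
    ``cold`` is the outdoor draw shifted by ``cold_offset`` (a colder
    site). ``active_months``, if given, restricts the pattern to those
    calendar months; outside them the environment is ambient.
    """

    name: str
    pattern: tuple[str, ...]
    greenhouse_min: float = 15.0
    chamber_setpoint: float = 18.0
    cold_offset: float = -1.5
    active_months: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.pattern) != 7:
            raise ValueError("pattern must assign an environment to all 7 weekdays")
        for tag in self.pattern:
            if tag not in ENVIRONMENT_TAGS:
                raise ValueError(
                    f"unknown environment tag {tag!r}; expected one of {ENVIRONMENT_TAGS}"
                )
        object.__setattr__(self, "pattern", tuple(self.pattern))


def _weekly(greenhouse: int = 0, chamber: int = 0, cold: int = 0) -> tuple[str, ...]:
    """Pattern with the given days/week in each controlled environment."""
    tags = (
        ["greenhouse"] * greenhouse + ["chamber"] * chamber + ["cold"] * cold
    )
    tags += ["ambient"] * (7 - len(tags))
    if len(tags) != 7:
        raise ValueError("days/week sum to more than 7")
    return tuple(tags)


def standard_schedules() -> dict[str, TreatmentSchedule]:
    """The standard trial regimes: days/week in each environment.

    Warm = 7 d greenhouse; Warm plus Cool Interruption = 6 d greenhouse +
    1 d outside; Ambient plus Warm 1/2 = 1/2 d greenhouse; Ambient = all
    outside; Cold = all at a colder site; Force Early/Late = 4 d in an
    18 degC chamber + 3 d outside for a six-week window (Nov-Dec or
    Jan-Feb), otherwise ambient.
    """
    return {
        "warm": TreatmentSchedule("warm", _weekly(greenhouse=7)),
        "warm_cool_interruption": TreatmentSchedule(
            "warm_cool_interruption", _weekly(greenhouse=6)
        ),
        "ambient_warm1": TreatmentSchedule("ambient_warm1", _weekly(greenhouse=1)),
        "ambient_warm2": TreatmentSchedule("ambient_warm2", _weekly(greenhouse=2)),
        "ambient": TreatmentSchedule("ambient", _weekly()),
        "cold": TreatmentSchedule("cold", _weekly(cold=7)),
        "force_early": TreatmentSchedule(
            "force_early", _weekly(chamber=4), active_months=(11, 12)
        ),
        "force_late": TreatmentSchedule(
            "force_late", _weekly(chamber=4), active_months=(1, 2)
        ),
    }


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _hourly_index(season_start, n_days: int) -> pd.DatetimeIndex:
    """Hourly record times; each record closes the hour ending at it."""
    start = pd.Timestamp(_as_datetime(season_start))
    return pd.date_range(
        start + pd.Timedelta(hours=1), periods=n_days * 24, freq="h"
    )


def _ambient_temps(
    climate: AmbientClimate, index: pd.DatetimeIndex, rng: np.random.Generator
) -> np.ndarray:
    doy = index.dayofyear.to_numpy(float)
    hour = index.hour.to_numpy(float)
    seasonal = -climate.seasonal_amp * np.cos(
        2 * np.pi * (doy - climate.coldest_doy) / 365.25
    )
    diurnal = climate.diurnal_amp * np.cos(
        2 * np.pi * (hour - climate.warmest_hour) / 24.0
    )
    if climate.noise_sd > 0:
        innov_sd = climate.noise_sd * np.sqrt(1 - climate.noise_ar1**2)
        eps = rng.normal(0.0, innov_sd, size=len(index))
        noise = lfilter([1.0], [1.0, -climate.noise_ar1], eps)
    else:
        noise = 0.0
    return climate.annual_mean + seasonal + diurnal + noise


def generate_ambient_series(
    climate: AmbientClimate,
    season_start,
    n_days: int,
    seed,
    label: str = "ambient",
) -> TemperatureSeries:
    """Hourly outdoor series of ``n_days`` starting at ``season_start``."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    index = _hourly_index(season_start, n_days)
    temps = _ambient_temps(climate, index, _rng(seed))
    return TemperatureSeries(index, temps, 1.0, label)


def generate_treatment_series(
    schedule: TreatmentSchedule,
    climate: AmbientClimate,
    season_start,
    n_days: int,
    seed,
) -> TemperatureSeries:
    """Hourly series for a treatment following its weekly pattern.

    The underlying ambient draw uses the same seed as
    :func:`generate_ambient_series`, so an all-ambient schedule
    reproduces the ambient series exactly.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    index = _hourly_index(season_start, n_days)
    ambient = _ambient_temps(climate, index, _rng(seed))
    # record at t closes the hour (t-1h, t]; attribute it to the weekday of t-1h
    interval_start = index - pd.Timedelta(hours=1)
    weekday = interval_start.weekday.to_numpy()
    env = np.array([schedule.pattern[w] for w in weekday])
    if schedule.active_months is not None:
        inactive = ~np.isin(interval_start.month.to_numpy(), schedule.active_months)
        env = np.where(inactive, "ambient", env)
    temps = ambient.copy()
    temps[env == "greenhouse"] = np.maximum(
        ambient[env == "greenhouse"], schedule.greenhouse_min
    )
    temps[env == "chamber"] = schedule.chamber_setpoint
    temps[env == "cold"] = ambient[env == "cold"] + schedule.cold_offset
    return TemperatureSeries(index, temps, 1.0, schedule.name)


def simulate_budburst_observations(
    series: TemperatureSeries,
    true_line: PossibilityLine,
    curves: tuple[EffectivenessCurve, EffectivenessCurve],
    n_seedlings: int = 24,
    sigma: float = 0.05,
    check_interval_days: int = 7,
    seed=0,
    season_start=None,
) -> BudburstObservationSet:
    """Simulate periodic budburst checks for seedlings on one treatment.

    Seedling *i* draws a lognormal multiplier ``m_i = exp(N(0, sigma))``
    on its forcing requirement; its budburst moment is the first record at
    which accumulated forcing reaches ``m_i * required_forcing(true_line,
    accumulated chilling)``. Observations are emitted only on check dates
    (every ``check_interval_days`` from the season start); seedlings whose
    condition is never met within the series never burst.
    """
    if n_seedlings < 1:
        raise ValueError("n_seedlings must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if season_start is None:
        season_start = (
            series.timestamps[0] - pd.Timedelta(hours=series.step_hours)
        ).to_pydatetime()
    chilling, forcing = curves
    traj = accumulate_units(series, chilling, forcing, season_start)
    req = np.asarray(required_forcing(true_line, traj.chill_units))
    rng = _rng(seed)
    multipliers = np.exp(rng.normal(0.0, sigma, size=n_seedlings))
    start = pd.Timestamp(_as_datetime(season_start))
    end = traj.timestamps[-1]
    check_dates = pd.date_range(
        start + pd.Timedelta(days=check_interval_days),
        end,
        freq=pd.Timedelta(days=check_interval_days),
    )
    seedlings = []
    for i, m in enumerate(multipliers):
        with np.errstate(invalid="ignore"):
            met = traj.force_units >= m * req
        moment = traj.timestamps[int(np.argmax(met))] if met.any() else None
        checks = tuple(
            (d.to_pydatetime(), moment is not None and moment <= d)
            for d in check_dates
        )
        seedlings.append(SeedlingRecord(f"{series.label or 'trt'}-{i:03d}", checks))
    return BudburstObservationSet(series.label or "treatment", tuple(seedlings))


def generate_station_gradient(
    n_stations: int,
    mean_range: tuple[float, float],
    deltas: MonthlyDeltas,
    seed,
    n_seasons: int = 8,
    n_days: int = 300,
    first_season_year: int = 2000,
    climate: AmbientClimate | None = None,
) -> list[StationRecord]:
    """Stations whose annual means span ``mean_range`` (mild to cold).

    Each station gets ``n_seasons`` independent hourly seasons starting
    November 1 and the shared warming ``deltas``. Along the gradient the
    annual mean falls while elevation and the seasonal amplitude rise:
    mild-coastal sites are maritime (damped annual cycle, winters near
    the annual mean) and cold sites montane/continental (large annual
    cycle), as on a coast-to-mountains transect.
    """
    if n_stations < 2:
        raise ValueError("n_stations must be >= 2")
    lo, hi = float(mean_range[0]), float(mean_range[1])
    base = climate or olympia_ambient()
    means = np.linspace(lo, hi, n_stations)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_stations)
    stations = []
    mn, mx = sorted((lo, hi))
    for k, (mean, child) in enumerate(zip(means, children)):
        # colder sites are more continental: larger seasonal amplitude
        amp = float(np.interp(mean, (mn, mx), (8.5, 3.5))) if mx > mn else base.seasonal_amp
        clim = replace(base, annual_mean=float(mean), seasonal_amp=amp)
        season_seeds = child.spawn(n_seasons)
        seasons = tuple(
            generate_ambient_series(
                clim,
                dt.datetime(first_season_year + j, 11, 1),
                n_days,
                s,
                label=f"station{k:03d}-{first_season_year + j}",
            )
            for j, s in enumerate(season_seeds)
        )
        frac = k / (n_stations - 1)
        stations.append(
            StationRecord(
                station_id=f"SYN{k:03d}",
                lat=43.0 + 4.0 * frac,
                lon=-123.0,
                elev_m=float(
                    np.interp(mean, sorted((lo, hi)), (1500.0, 10.0))
                ),
                seasons=seasons,
                deltas=deltas,
            )
        )
    return stations
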