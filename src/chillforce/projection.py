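"""Budburst-date prediction and climate-warming projection.

Given an hourly temperature series, effectiveness curves and a possibility
line, the predicted budburst date is the first time at which the cumulative
(chilling, forcing) trajectory crosses onto or above the line. Because both
cumulative unit series are nondecreasing and the required forcing is
nonincreasing in chilling, the crossing is unique: once possible, always
possible.

Warming scenarios are expressed as twelve monthly mean-temperature deltas
(degC) added to the contemporary hourly records; the change in budburst
date is the difference between the multi-season mean day-of-year under the
shifted and unshifted climates.

Day-of-year is reported with 1 = January 1 of the calendar year following
the season start; a December budburst therefore yields a day <= 0 (Dec 31
is day 0), which keeps multi-season averaging on one continuous axis.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .accumulation import (
    SeriesError,
    TemperatureSeries,
    _as_datetime,
    accumulate_units,
)
from .curves import EffectivenessCurve
from .possibility import PossibilityLine, required_forcing

__all__ = [
    "MonthlyDeltas",
    "StationRecord",
    "predict_budburst_date",
    "budburst_day_of_year",
    "mean_budburst_day",
    "apply_monthly_deltas",
    "budburst_change",
    "batch_project",
]


@dataclass(frozen=True)
class MonthlyDeltas:
    """Monthly mean-temperature increments (degC), months 1..12."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) != 12:
            raise ValueError(f"need exactly 12 monthly deltas, got {len(vals)}")
        if not all(np.isfinite(vals)):
            raise ValueError("deltas must be finite")
        object.__setattr__(self, "values", vals)

    @classmethod
    def uniform(cls, delta: float) -> "MonthlyDeltas":
        return cls((float(delta),) * 12)

    @classmethod
    def zero(cls) -> "MonthlyDeltas":
        return cls.uniform(0.0)

    def for_month(self, month: int) -> float:
        return self.values[month - 1]


@dataclass(frozen=True)
class StationRecord:
    """A weather station: coordinates, per-season series, warming deltas."""

    station_id: str
    lat: float
    lon: float
    elev_m: float
    seasons: tuple[TemperatureSeries, ...]  # one per available season/year
    deltas: MonthlyDeltas | None = None

    def __post_init__(self) -> None:
        if not self.seasons:
            raise ValueError(f"station {self.station_id}: no seasons")
        if not (-90 <= self.lat <= 90) or not (-180 <= self.lon <= 360):
            raise ValueError(f"station {self.station_id}: implausible coordinates")
        object.__setattr__(self, "seasons", tuple(self.seasons))


def predict_budburst_date(
    series: TemperatureSeries,
    line: PossibilityLine,
    curves: tuple[EffectivenessCurve, EffectivenessCurve],
    season_start,
) -> dt.datetime | None:
    """First time the accumulated trajectory makes budburst possible.

    Returns ``None`` if the possibility condition is never satisfied within
    the series (budburst impossible that season).
    """
    start = _as_datetime(season_start)
    if series.timestamps[-1] < pd.Timestamp(start) + pd.Timedelta(days=30):
        raise SeriesError("series must extend at least 30 days past season start")
    chilling, forcing = curves
    traj = accumulate_units(series, chilling, forcing, start)
    req = required_forcing(line, traj.chill_units)
    possible = traj.force_units >= req
    if not possible.any():
        return None
    i = int(np.argmax(possible))  # first True; condition is monotone in time
    return traj.timestamps[i].to_pydatetime()


def budburst_day_of_year(date: dt.datetime, season_start) -> float:
    """Day-of-year of ``date`` relative to the year after the season start.

    1 = January 1 of the calendar year following ``season_start``; late-
    autumn budburst gives values <= 0 on the same continuous axis.
    """
    start = _as_datetime(season_start)
    jan1 = dt.datetime(start.year + 1, 1, 1)
    delta = pd.Timestamp(date) - pd.Timestamp(jan1)
    return delta.total_seconds() / 86400.0 + 1.0


def _season_start_for(series: TemperatureSeries, month: int, day: int) -> dt.datetime:
    """Season start (month-day) falling within the series' first year."""
    t0 = series.timestamps[0]
    candidates = [dt.datetime(y, month, day) for y in (t0.year - 1, t0.year, t0.year + 1)]
    return min(candidates, key=lambda c: abs(pd.Timestamp(c) - t0))


def mean_budburst_day(
    station: StationRecord,
    line: PossibilityLine,
    curves: tuple[EffectivenessCurve, EffectivenessCurve],
    season_start_month: int = 11,
    season_start_day: int = 1,
    deltas: MonthlyDeltas | None = None,
) -> tuple[float | None, int]:
    """Mean predicted budburst day-of-year across a station's seasons.

    Seasons with no predicted budburst are excluded from the mean and
    counted; returns ``(mean_day or None, n_failed_seasons)``.
    """
    days: list[float] = []
    failed = 0
    for season in station.seasons:
        if deltas is not None:
            season = apply_monthly_deltas(season, deltas)
        start = _season_start_for(season, season_start_month, season_start_day)
        date = predict_budburst_date(season, line, curves, start)
        if date is None:
            failed += 1
        else:
            days.append(budburst_day_of_year(date, start))
    if not days:
        return None, failed
    return float(np.mean(days)), failed


def apply_monthly_deltas(
    series: TemperatureSeries, deltas: MonthlyDeltas
) -> TemperatureSeries:
    """Add each record's calendar-month delta to its temperature."""
    shifts = np.asarray(deltas.values)[series.timestamps.month - 1]
    return TemperatureSeries(
        series.timestamps,
        series.temps_c + shifts,
        series.step_hours,
        series.label,
    )


def budburst_change(
    station: StationRecord,
    line: PossibilityLine,
    curves: tuple[EffectivenessCurve, EffectivenessCurve],
    season_start_month: int = 11,
    season_start_day: int = 1,
) -> dict:
    """Mean budburst day under current vs delta-shifted climate.

    Returns ``{"current_day", "future_day", "change_days", "status"}``;
    ``change_days = future - current`` (negative = earlier). Missing
    predictions propagate as ``None`` with a status of
    ``no_burst_current``, ``no_burst_future`` or ``no_burst_both``.
    """
    if station.deltas is None:
        raise ValueError(f"station {station.station_id} has no warming deltas")
    current, _ = mean_budburst_day(
        station, line, curves, season_start_month, season_start_day
    )
    future, _ = mean_budburst_day(
        station, line, curves, season_start_month, season_start_day,
        deltas=station.deltas,
    )
    if current is None and future is None:
        status = "no_burst_both"
    elif current is None:
        status = "no_burst_current"
    elif future is None:
        status = "no_burst_future"
    else:
        status = "ok"
    change = future - current if status == "ok" else None
    return {
        "current_day": current,
        "future_day": future,
        "change_days": change,
        "status": status,
    }


def batch_project(
    stations: Sequence[StationRecord],
    line: PossibilityLine,
    curves: tuple[EffectivenessCurve, EffectivenessCurve],
    season_start_month: int = 11,
    season_start_day: int = 1,
) -> pd.DataFrame:
    """Project budburst change for every station; one row per station.

    Per-station failures are recorded in the ``status`` column and never
    abort the batch. Rows are ordered by station id.
    """
    if not stations:
        raise ValueError("no stations supplied")
    rows = []
    for station in sorted(stations, key=lambda s: s.station_id):
        row = {
            "station_id": station.station_id,
            "lat": station.lat,
            "lon": station.lon,
            "elev_m": station.elev_m,
        }
        try:
            res = budburst_change(
                station, line, curves, season_start_month, season_start_day
            )
            row.update(
                current_doy=res["current_day"],
                future_doy=res["future_day"],
                change_days=res["change_days"],
                status=res["status"],
            )
        except Exception as err:  # noqa: BLE001 - isolate per-station failures
            row.update(
                current_doy=None, future_doy=None, change_days=None,
                status=f"error: {err}",
            )
        rows.append(row)
    return pd.DataFrame(rows)
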