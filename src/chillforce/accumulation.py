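"""Cumulative chilling/forcing unit trajectories from hourly temperature series.

Each record in a :class:`TemperatureSeries` is taken to report the mean air
temperature over the step interval *ending* at its timestamp. Accumulation
multiplies the step length in hours by the temperature's efficacy under the
relevant effectiveness curve, so units are effectiveness-weighted hours.
Both chilling and forcing accumulate in parallel from the season start
(default November 1) until the end of the series -- there is no spring
cutoff on chilling.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import EffectivenessCurve

__all__ = [
    "TemperatureSeries",
    "UnitTrajectory",
    "SeriesError",
    "GapError",
    "fill_gaps",
    "accumulate_units",
    "units_at",
]

TEMP_BOUNDS = (-60.0, 60.0)  # sanity bounds, degC
DEFAULT_MAX_GAP_HOURS = 72.0


class SeriesError(ValueError):
    """Invalid temperature series input."""


class GapError(SeriesError):
    """A gap in the series exceeds the fillable limit."""


@dataclass(frozen=True)
class TemperatureSeries:
    """A regular (after gap-fill) time series of air temperatures.

    Parameters
    ----------
    timestamps
        Strictly increasing naive local-standard-time stamps.
    temps_c
        Air temperature, degC, one per timestamp; finite, within sanity
        bounds of [-60, 60].
    step_hours
        Nominal record spacing in hours (1.0 or 0.5 typical).
    label
        Site or treatment label, informational.
    """

    timestamps: pd.DatetimeIndex
    temps_c: np.ndarray
    step_hours: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        temps = np.asarray(self.temps_c, dtype=float)
        if len(ts) != len(temps):
            raise SeriesError("timestamps and temps_c must have equal length")
        if len(ts) == 0:
            raise SeriesError("series is empty")
        if ts.tz is not None:
            raise SeriesError("timestamps must be naive local standard time")
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            raise SeriesError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(temps)):
            raise SeriesError("temperatures must be finite")
        if temps.min() < TEMP_BOUNDS[0] or temps.max() > TEMP_BOUNDS[1]:
            raise SeriesError(
                f"temperatures outside sanity bounds {TEMP_BOUNDS} degC"
            )
        if not self.step_hours > 0:
            raise SeriesError("step_hours must be positive")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "temps_c", temps)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def is_regular(self) -> bool:
        """True if consecutive records are exactly ``step_hours`` apart."""
        if len(self) < 2:
            return True
        deltas = np.diff(self.timestamps.view("int64")) / 3.6e12
        return bool(np.allclose(deltas, self.step_hours, atol=1e-9))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "temp_c": self.temps_c})

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["temp_c"] = df["temp_c"].map(lambda x: format(x, ".9g"))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, step_hours: float | None = None, label: str = ""
    ) -> "TemperatureSeries":
        """Read ``timestamp,temp_c`` CSV; infers the step if not given."""
        df = pd.read_csv(path)
        for col in ("timestamp", "temp_c"):
            if col not in df.columns:
                raise SeriesError(f"input CSV missing required column '{col}'")
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        if step_hours is None:
            if len(ts) < 2:
                step_hours = 1.0
            else:
                step_hours = float(
                    np.median(np.diff(ts.view("int64"))) / 3.6e12
                )
        return cls(ts, df["temp_c"].to_numpy(float), step_hours, label or str(path))


def fill_gaps(
    series: TemperatureSeries, max_gap: float = DEFAULT_MAX_GAP_HOURS
) -> TemperatureSeries:
    """Fill missing records by linear interpolation in time.

    Gaps of at most ``max_gap`` hours are filled on the nominal step grid;
    a longer gap raises :class:`GapError` naming its location and length.
    A complete series is returned unchanged.
    """
    step = pd.Timedelta(hours=series.step_hours)
    deltas = np.diff(series.timestamps.view("int64")) / 3.6e12
    if np.allclose(deltas, series.step_hours, atol=1e-9):
        return series
    too_big = np.where(deltas > max_gap + 1e-9)[0]
    if too_big.size:
        i = int(too_big[0])
        raise GapError(
            f"gap of {deltas[i]:.1f} h starting {series.timestamps[i]} "
            f"exceeds max_gap={max_gap} h"
        )
    full_index = pd.date_range(
        series.timestamps[0], series.timestamps[-1], freq=step
    )
    s = pd.Series(series.temps_c, index=series.timestamps)
    s = s.reindex(full_index.union(series.timestamps)).interpolate(method="time")
    s = s.reindex(full_index)
    return TemperatureSeries(
        full_index, s.to_numpy(float), series.step_hours, series.label
    )


@dataclass(frozen=True)
class UnitTrajectory:
    """Cumulative chilling/forcing units aligned to a series' timestamps.

    ``chill_units[i]`` (resp. ``force_units[i]``) is the total accumulated
    over all record intervals ending in ``(season_start, timestamps[i]]``;
    both are nondecreasing and zero at or before the season start.
    """

    timestamps: pd.DatetimeIndex
    chill_units: np.ndarray
    force_units: np.ndarray
    season_start: dt.datetime
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "chill_units": self.chill_units,
                "force_units": self.force_units,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        for col in ("chill_units", "force_units"):
            df[col] = df[col].map(lambda x: format(x, ".9g"))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, season_start=None) -> "UnitTrajectory":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        ts = pd.DatetimeIndex(df["timestamp"])
        if season_start is None:
            season_start = ts[0].to_pydatetime()
        return cls(
            ts,
            df["chill_units"].to_numpy(float),
            df["force_units"].to_numpy(float),
            _as_datetime(season_start),
        )


def _as_datetime(when) -> dt.datetime:
    if isinstance(when, dt.datetime):
        return when
    if isinstance(when, dt.date):
        return dt.datetime(when.year, when.month, when.day)
    return pd.Timestamp(when).to_pydatetime()


def accumulate_units(
    series: TemperatureSeries,
    chilling: EffectivenessCurve,
    forcing: EffectivenessCurve,
    season_start,
) -> UnitTrajectory:
    """Accumulate chilling and forcing units from ``season_start``.

    Each record contributes ``efficacy(T) * step_hours`` to the relevant
    cumulative sum; records whose interval ends at or before the season
    start contribute nothing. Chilling accumulates to the end of the series
    (no spring cutoff).
    """
    start = _as_datetime(season_start)
    if series.timestamps[-1] <= pd.Timestamp(start):
        raise SeriesError(
            f"series ends {series.timestamps[-1]} before season start {start}"
        )
    if not series.is_regular:
        raise SeriesError("series has gaps; run fill_gaps first")
    active = (series.timestamps > pd.Timestamp(start)).astype(float)
    chill_inc = chilling(series.temps_c) * series.step_hours * active
    force_inc = forcing(series.temps_c) * series.step_hours * active
    return UnitTrajectory(
        series.timestamps,
        np.cumsum(chill_inc),
        np.cumsum(force_inc),
        start,
        series.label,
    )


def units_at(trajectory: UnitTrajectory, when) -> tuple[float, float]:
    """Cumulative (chilling, forcing) units at the last timestamp <= ``when``.

    Before the season start this is ``(0.0, 0.0)``; past the end of the
    trajectory it is a range error.
    """
    ts = pd.Timestamp(_as_datetime(when))
    if ts < pd.Timestamp(trajectory.season_start):
        return 0.0, 0.0
    if ts > trajectory.timestamps[-1]:
        raise ValueError(f"{when} is after the trajectory end {trajectory.timestamps[-1]}")
    i = int(trajectory.timestamps.searchsorted(ts, side="right")) - 1
    if i < 0:
        return 0.0, 0.0
    return float(trajectory.chill_units[i]), float(trajectory.force_units[i])
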