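import datetime as dt

import numpy as np
import pandas as pd
import pytest

from chillforce import (
    PossibilityLine,
    TemperatureSeries,
    default_curves,
    olympia_ambient,
)

SEASON_START = dt.datetime(2011, 11, 1)

# Reference line used across the simulation studies: spans the unit scales
# the standard treatment regimes produce under the Olympia-like climate,
# with an obligate chilling threshold.
TRUE_LINE = PossibilityLine(a0=300.0, a1=8.5, a2=-0.0012, c_min=300.0, label="true")


@pytest.fixture(scope="session")
def curves():
    return default_curves()


@pytest.fixture(scope="session")
def climate():
    return olympia_ambient()


@pytest.fixture
def season_start():
    return SEASON_START


@pytest.fixture
def true_line():
    return TRUE_LINE


def make_constant_series(
    temp_c: float, n_hours: int, start: dt.datetime = SEASON_START, step_hours: float = 1.0
) -> TemperatureSeries:
    """Constant-temperature series whose first record closes the first step."""
    index = pd.date_range(
        pd.Timestamp(start) + pd.Timedelta(hours=step_hours),
        periods=n_hours,
        freq=pd.Timedelta(hours=step_hours),
    )
    return TemperatureSeries(index, np.full(n_hours, float(temp_c)), step_hours, "const")


def make_sinusoidal_series(
    seed: int, n_days: int = 120, start: dt.datetime = SEASON_START
) -> TemperatureSeries:
    """Seeded synthetic winter series: seasonal + diurnal cycle + noise."""
    rng = np.random.default_rng(seed)
    n = n_days * 24
    index = pd.date_range(pd.Timestamp(start) + pd.Timedelta(hours=1), periods=n, freq="h")
    hours = np.arange(n)
    temps = (
        5.0
        - 6.0 * np.cos(2 * np.pi * hours / (24 * 365.25))
        + 4.0 * np.cos(2 * np.pi * (hours % 24 - 15) / 24)
        + rng.normal(0, 2.0, n)
    )
    return TemperatureSeries(index, temps, 1.0, f"sin-{seed}")


@pytest.fixture
def sinusoidal_series():
    return make_sinusoidal_series(42)
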