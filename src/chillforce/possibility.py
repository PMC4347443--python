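"""Possibility lines: the chilling-forcing tradeoff curve for budburst.

A possibility line gives the forcing units required for 50% budburst as a
declining exponential function of the chilling units received,

    required_forcing(c) = a0 + exp(a1 + a2 * c),        a0 >= 0, a2 <= 0,

so well-chilled plants need less forcing and the requirement approaches the
asymptote ``a0`` at high chilling. Combinations on or above the line permit
budburst; combinations below it do not. Species with an obligate chilling
requirement carry an additional threshold ``c_min`` below which budburst is
impossible regardless of forcing.

The module also extracts per-treatment (chilling, forcing) points at the
date of 50% budburst from repeated per-seedling observations, and fits
lines to those points by constrained nonlinear least squares.
"""

from __future__ import annotations

import datetime as dt
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .accumulation import UnitTrajectory, units_at

__all__ = [
    "PossibilityLine",
    "SeedlingRecord",
    "BudburstObservationSet",
    "TreatmentPoint",
    "FitError",
    "required_forcing",
    "is_budburst_possible",
    "fifty_percent_point",
    "fit_possibility_line",
]


class FitError(RuntimeError):
    """Possibility-line fit could not be performed or did not converge."""


@dataclass(frozen=True)
class PossibilityLine:
    """Parameters of the forcing-required-vs-chilling tradeoff curve.

    ``a0`` is the asymptotic minimum forcing (units, >= 0); ``a1`` the
    log-scale intercept of the exponential term; ``a2`` the per-chilling-
    unit decay rate (<= 0). ``c_min`` (chilling units), if positive, marks
    an obligate chilling requirement: below it budburst is impossible.
    """

    a0: float
    a1: float
    a2: float
    c_min: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.a0 >= 0):
            raise ValueError(f"a0 must be >= 0, got {self.a0}")
        if not (self.a2 <= 0):
            raise ValueError(f"a2 must be <= 0, got {self.a2}")
        if not (self.c_min >= 0):
            raise ValueError(f"c_min must be >= 0, got {self.c_min}")

    def required_forcing(self, chilling) -> np.ndarray | float:
        return required_forcing(self, chilling)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "a0": self.a0,
            "a1": self.a1,
            "a2": self.a2,
            "c_min": self.c_min,
        }

    def to_json(self, path: str | Path, fit: dict | None = None) -> None:
        payload = self.to_dict()
        if fit is not None:
            payload["fit"] = fit
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PossibilityLine":
        d = json.loads(Path(path).read_text())
        return cls(
            a0=float(d["a0"]),
            a1=float(d["a1"]),
            a2=float(d["a2"]),
            c_min=float(d.get("c_min", 0.0)),
            label=str(d.get("label", "")),
        )


def required_forcing(line: PossibilityLine, chilling) -> np.ndarray | float:
    """Forcing units required for budburst at the given chilling units.

    Returns ``a0 + exp(a1 + a2 * chilling)``, or ``+inf`` where chilling is
    below the obligate threshold ``c_min``.
    """
    c = np.asarray(chilling, dtype=float)
    if np.any(c < 0):
        raise ValueError("chilling must be nonnegative")
    with np.errstate(under="ignore"):
        req = line.a0 + np.exp(line.a1 + line.a2 * c)
    if line.c_min > 0:
        req = np.where(c < line.c_min, np.inf, req)
    return float(req) if np.isscalar(chilling) or req.ndim == 0 else req


def is_budburst_possible(line: PossibilityLine, chilling, forcing):
    """Whether (chilling, forcing) lies on or above the possibility line.

    The boundary is inclusive: forcing exactly equal to the requirement
    counts as budburst.
    """
    f = np.asarray(forcing, dtype=float)
    if np.any(f < 0):
        raise ValueError("forcing must be nonnegative")
    out = f >= required_forcing(line, chilling)
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SeedlingRecord:
    """Repeated budburst checks for one seedling."""

    seedling_id: str
    checks: tuple[tuple[dt.datetime, bool], ...]  # (check date, burst)
    abnormal: bool = False  # re-coded: parted scales but never elongated
    lot: str = ""

    def __post_init__(self) -> None:
        dates = [c[0] for c in self.checks]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"seedling {self.seedling_id}: check dates must increase")
        # burst is absorbing: once yes, later checks must be yes
        seen = False
        fixed = []
        for date, burst in self.checks:
            seen = seen or bool(burst)
            fixed.append((date, seen))
        object.__setattr__(self, "checks", tuple(fixed))

    def burst_by(self, when: dt.datetime) -> bool:
        """Burst status as of ``when`` (abnormal seedlings never count)."""
        if self.abnormal:
            return False
        status = False
        for date, burst in self.checks:
            if date > when:
                break
            status = burst
        return status


@dataclass(frozen=True)
class BudburstObservationSet:
    """All seedlings of one treatment, checked on shared dates."""

    treatment: str
    seedlings: tuple[SeedlingRecord, ...]

    def __post_init__(self) -> None:
        if not self.seedlings:
            raise ValueError("observation set is empty")
        object.__setattr__(self, "seedlings", tuple(self.seedlings))

    @property
    def check_dates(self) -> list[dt.datetime]:
        dates: set[dt.datetime] = set()
        for s in self.seedlings:
            dates.update(d for d, _ in s.checks)
        return sorted(dates)

    def fraction_burst(self, when: dt.datetime) -> float:
        """Fraction of seedlings burst by ``when``; abnormal count as not."""
        n = len(self.seedlings)
        return sum(s.burst_by(when) for s in self.seedlings) / n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.seedlings:
            for date, burst in s.checks:
                rows.append(
                    {
                        "treatment": self.treatment,
                        "seedling_id": s.seedling_id,
                        "lot": s.lot,
                        "check_date": date,
                        "burst": int(burst),
                        "abnormal": int(s.abnormal),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BudburstObservationSet":
        treatment = str(df["treatment"].iloc[0])
        seedlings = []
        for sid, grp in df.groupby("seedling_id", sort=True):
            grp = grp.sort_values("check_date")
            checks = tuple(
                (pd.Timestamp(d).to_pydatetime(), bool(b))
                for d, b in zip(grp["check_date"], grp["burst"])
            )
            abnormal = bool(grp["abnormal"].any()) if "abnormal" in grp else False
            lot = str(grp["lot"].iloc[0]) if "lot" in grp else ""
            seedlings.append(SeedlingRecord(str(sid), checks, abnormal, lot))
        return cls(treatment, tuple(seedlings))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BudburstObservationSet":
        return cls.from_frame(pd.read_csv(path, parse_dates=["check_date"]))


@dataclass(frozen=True)
class TreatmentPoint:
    """(chilling, forcing) at the date of 50% budburst for one treatment."""

    treatment: str
    chill_units: float
    force_units: float
    reached_50: bool = True
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.chill_units < 0 or self.force_units < 0:
            raise ValueError("units must be nonnegative")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def fifty_percent_point(
    observations: BudburstObservationSet, trajectory: UnitTrajectory
) -> TreatmentPoint:
    """Extract the 50%-budburst (chilling, forcing) point for a treatment.

    The fraction burst is evaluated at each check date (abnormal seedlings
    count as never burst). The 50% date is the first check at which the
    fraction reaches 0.5, linearly interpolated between the flanking
    checks when the crossing falls between them. If the final fraction
    never reaches 0.5 the point is returned with ``reached_50=False`` and
    the units at the last check.
    """
    dates = observations.check_dates
    if not dates:
        raise ValueError("observation set has no check dates")
    fracs = [observations.fraction_burst(d) for d in dates]
    cross = next((i for i, f in enumerate(fracs) if f >= 0.5), None)
    if cross is None:
        chill, force = units_at(trajectory, dates[-1])
        return TreatmentPoint(observations.treatment, chill, force, reached_50=False)
    if cross == 0:
        when = dates[0]
    else:
        f0, f1 = fracs[cross - 1], fracs[cross]
        t0, t1 = dates[cross - 1], dates[cross]
        frac_of_interval = (0.5 - f0) / (f1 - f0)
        when = t0 + (t1 - t0) * frac_of_interval
    chill, force = units_at(trajectory, when)
    return TreatmentPoint(observations.treatment, chill, force, reached_50=True)


def _initial_guess(
    chill: np.ndarray, force: np.ndarray
) -> tuple[float, float, float]:
    a0 = max(0.0, 0.8 * float(force.min()))
    excess = np.maximum(force - a0, 1e-6)
    # log-linear regression of the excess over a0 gives a1, a2
    if len(np.unique(chill)) >= 2:
        slope, intercept = np.polyfit(chill, np.log(excess), 1)
        a2 = min(0.0, float(slope))
        a1 = float(intercept)
    else:
        a2 = 0.0
        a1 = float(np.log(excess.mean()))
    return a0, a1, a2


def fit_possibility_line(
    points: Sequence[TreatmentPoint],
    obligate: bool = False,
    weights: Sequence[float] | None = None,
    asymmetric: bool = False,
    c_min_factor: float = 0.5,
    label: str = "",
) -> tuple[PossibilityLine, dict]:
    """Fit a possibility line to treatment points by constrained NLS.

    Minimises ``sum w_i (force_i - (a0 + exp(a1 + a2*chill_i)))**2``
    subject to ``a0 >= 0`` and ``a2 <= 0``, using points that reached 50%
    budburst. With ``asymmetric=True`` negative residuals (points below
    the line) are given double weight, pushing the line beneath the point
    cloud. Points that never reached 50% are used only as feasibility
    checks: the fitted line should pass above/left of them, and a warning
    is emitted if it does not.

    With ``obligate=True`` the line is given an obligate chilling
    threshold ``c_min = c_min_factor * min(chilling among reached-50
    points)``, below which budburst is impossible.

    Returns the fitted line and a diagnostics dict with the residual sum
    of squares, per-point residuals and a convergence flag.
    """
    fit_pts = [p for p in points if p.reached_50]
    if len(fit_pts) < 3:
        raise FitError(
            f"need >= 3 points that reached 50% budburst, got {len(fit_pts)}"
        )
    chill = np.array([p.chill_units for p in fit_pts])
    force = np.array([p.force_units for p in fit_pts])
    if len(np.unique(chill)) < 2:
        raise FitError("fitting points span fewer than 2 distinct chilling levels")
    if weights is None:
        w = np.array([p.weight for p in fit_pts])
    else:
        if len(weights) != len(points):
            raise FitError("weights must match the number of points")
        w = np.array(
            [wi for wi, p in zip(weights, points) if p.reached_50], dtype=float
        )
    sqrt_w = np.sqrt(w)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a0, a1, a2 = theta
        with np.errstate(over="ignore", under="ignore"):
            r = force - (a0 + np.exp(a1 + a2 * chill))
        r = sqrt_w * np.where(np.isfinite(r), r, 1e12)
        if asymmetric:
            r = np.where(r < 0, r * np.sqrt(2.0), r)
        return r

    x0 = np.array(_initial_guess(chill, force))
    bounds = ([0.0, -np.inf, -np.inf], [np.inf, np.inf, 0.0])
    x0 = np.clip(x0, bounds[0], bounds[1])
    sol = least_squares(residuals, x0, bounds=bounds, method="trf", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14, max_nfev=20000)
    if not sol.success:
        raise FitError(f"non-convergence: {sol.message}; x={sol.x}, cost={sol.cost}")
    a0, a1, a2 = map(float, sol.x)
    c_min = 0.0
    if obligate:
        c_min = float(c_min_factor * chill.min())
    line = PossibilityLine(a0=a0, a1=a1, a2=a2, c_min=c_min, label=label)
    resid = force - (a0 + np.exp(a1 + a2 * chill))
    diagnostics = {
        "rss": float(np.sum(w * resid**2)),
        "residuals": resid.tolist(),
        "n_points": len(fit_pts),
        "converged": bool(sol.success),
    }
    # never-reached points must lie strictly below/left of the line
    for p in points:
        if p.reached_50:
            continue
        if is_budburst_possible(line, p.chill_units, p.force_units):
            warnings.warn(
                f"treatment {p.treatment!r} never reached 50% budburst but its "
                f"point ({p.chill_units:.0f}, {p.force_units:.0f}) lies above "
                "the fitted line",
                stacklevel=2,
            )
    return line, diagnostics


def points_to_csv(points: Sequence[TreatmentPoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "treatment": p.treatment,
                "chill_units": format(p.chill_units, ".9g"),
                "force_units": format(p.force_units, ".9g"),
                "reached_50": int(p.reached_50),
                "weight": p.weight,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def points_from_csv(path: str | Path) -> list[TreatmentPoint]:
    df = pd.read_csv(path)
    return [
        TreatmentPoint(
            str(r.treatment),
            float(r.chill_units),
            float(r.force_units),
            bool(r.reached_50),
            float(getattr(r, "weight", 1.0)),
        )
        for r in df.itertuples(index=False)
    ]
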