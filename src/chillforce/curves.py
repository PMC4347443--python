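"""Temperature-effectiveness curves for chilling and forcing.

A curve maps air temperature (degC) to a unitless efficacy in [0, 1] that
weights each hour's contribution to cumulative chilling or forcing units.
Curves are piecewise-linear between user-supplied knots; outside the knot
span a constant value (default 0) applies.

The packaged defaults are a documented approximation of the qualitative
shape used in parallel-model dormancy work on Pacific Northwest conifers:
chilling efficacy is zero well below freezing, small just below 0 degC,
peaks near 1 in the low single digits degC, declines to a small positive
value above 10 degC and reaches zero by the mid-teens; forcing efficacy is
a sigmoid rising from ~0 near 0-3 degC to ~1 by 20-25 degC. They are
overridable via :func:`load_curves`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "EffectivenessCurve",
    "CurveConfigError",
    "default_chilling_curve",
    "default_forcing_curve",
    "load_curves",
]


class CurveConfigError(ValueError):
    """Raised when a curve definition violates its invariants."""


# Default knot tables: a qualitative approximation of the effectiveness
# shapes described for temperate conifers, not digitised calibration data.
_DEFAULT_CHILLING_KNOTS: tuple[tuple[float, float], ...] = (
    (-10.0, 0.00),
    (-5.0, 0.00),
    (-2.0, 0.10),
    (0.0, 0.80),
    (2.0, 1.00),
    (4.0, 1.00),
    (7.0, 0.85),
    (10.0, 0.40),
    (12.0, 0.25),
    (14.0, 0.10),
    (16.0, 0.00),
)

_DEFAULT_FORCING_KNOTS: tuple[tuple[float, float], ...] = (
    (-10.0, 0.00),
    (0.0, 0.00),
    (3.0, 0.05),
    (5.0, 0.15),
    (10.0, 0.50),
    (15.0, 0.85),
    (20.0, 0.97),
    (25.0, 1.00),
    (30.0, 1.00),
)


@dataclass(frozen=True)
class EffectivenessCurve:
    """Piecewise-linear temperature -> efficacy map.

    Parameters
    ----------
    kind
        ``"chilling"`` or ``"forcing"``; informational label.
    knots
        Ordered ``(temperature_degC, efficacy)`` pairs. Temperatures must be
        strictly increasing and efficacies must lie in [0, 1].
    outside_range_value
        Efficacy returned beyond the first/last knot temperature.
    """

    kind: str
    knots: tuple[tuple[float, float], ...]
    outside_range_value: float = 0.0
    _temps: np.ndarray = field(init=False, repr=False, compare=False)
    _effs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("chilling", "forcing"):
            raise CurveConfigError(f"kind must be 'chilling' or 'forcing', got {self.kind!r}")
        knots = tuple((float(t), float(e)) for t, e in self.knots)
        if len(knots) < 2:
            raise CurveConfigError("knots: at least two knots are required")
        temps = np.array([t for t, _ in knots])
        effs = np.array([e for _, e in knots])
        if not np.all(np.isfinite(temps)) or not np.all(np.isfinite(effs)):
            raise CurveConfigError("knots: temperatures and efficacies must be finite")
        if np.any(np.diff(temps) <= 0):
            raise CurveConfigError("knots: temperatures must be strictly increasing")
        if np.any(effs < 0.0) or np.any(effs > 1.0):
            bad = effs[(effs < 0.0) | (effs > 1.0)][0]
            raise CurveConfigError(f"knots: efficacy {bad} outside [0, 1]")
        if not (0.0 <= self.outside_range_value <= 1.0):
            raise CurveConfigError(
                f"outside_range_value {self.outside_range_value} outside [0, 1]"
            )
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "_temps", temps)
        object.__setattr__(self, "_effs", effs)

    def __call__(self, temperature) -> np.ndarray | float:
        """Evaluate efficacy at ``temperature`` (scalar or array, degC)."""
        t = np.asarray(temperature, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature must be finite")
        out = np.interp(t, self._temps, self._effs)
        outside = (t < self._temps[0]) | (t > self._temps[-1])
        out = np.where(outside, self.outside_range_value, out)
        return float(out) if np.isscalar(temperature) or out.ndim == 0 else out


def eval_effectiveness(curve: EffectivenessCurve, temperature) -> np.ndarray | float:
    """Functional alias for ``curve(temperature)``."""
    return curve(temperature)


def default_chilling_curve() -> EffectivenessCurve:
    return EffectivenessCurve("chilling", _DEFAULT_CHILLING_KNOTS)


def default_forcing_curve() -> EffectivenessCurve:
    return EffectivenessCurve("forcing", _DEFAULT_FORCING_KNOTS)


def default_curves() -> tuple[EffectivenessCurve, EffectivenessCurve]:
    """The packaged (chilling, forcing) curve pair."""
    return default_chilling_curve(), default_forcing_curve()


def _curve_from_mapping(kind: str, mapping: dict) -> EffectivenessCurve:
    if "knots" not in mapping:
        raise CurveConfigError(f"{kind}: missing 'knots'")
    knots = mapping["knots"]
    if not isinstance(knots, Iterable):
        raise CurveConfigError(f"{kind}.knots: expected a list of [T, e] pairs")
    pairs = []
    for i, item in enumerate(knots):
        item = list(item)
        if len(item) != 2:
            raise CurveConfigError(f"{kind}.knots[{i}]: expected a [T, e] pair")
        pairs.append((float(item[0]), float(item[1])))
    try:
        return EffectivenessCurve(
            kind, tuple(pairs), float(mapping.get("outside_range_value", 0.0))
        )
    except CurveConfigError as err:
        raise CurveConfigError(f"{kind}.{err}") from err


def load_curves(
    config: dict | str | Path | None = None,
) -> tuple[EffectivenessCurve, EffectivenessCurve]:
    """Load the (chilling, forcing) curve pair from a config.

    ``config`` may be a mapping ``{"chilling": {"knots": [[T, e], ...]},
    "forcing": {...}}``, a path to a JSON/YAML file holding such a mapping,
    the string ``"default"``, or ``None`` (packaged defaults).
    """
    if config is None or config == "default":
        return default_curves()
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text)  # YAML superset also parses JSON
    if not isinstance(config, dict):
        raise CurveConfigError("curve config must be a mapping")
    for key in ("chilling", "forcing"):
        if key not in config:
            raise CurveConfigError(f"missing '{key}' curve definition")
    chilling = _curve_from_mapping("chilling", config["chilling"])
    forcing = _curve_from_mapping("forcing", config["forcing"])
    return chilling, forcing


def curves_to_config(
    chilling: EffectivenessCurve, forcing: EffectivenessCurve
) -> dict:
    """Serialise a curve pair back to the config mapping form."""

    def enc(c: EffectivenessCurve) -> dict:
        return {
            "knots": [[t, e] for t, e in c.knots],
            "outside_range_value": c.outside_range_value,
        }

    return {"chilling": enc(chilling), "forcing": enc(forcing)}
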