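"""Drying-curve primitives: moisture series, moisture ratio, drying rate,
and equilibrium-endpoint detection.

A convective-drying run is recorded as dry-basis moisture content
``M_t`` (kg H2O per kg bone-dry solid) at fixed weighing intervals.  The
dimensionless moisture ratio

    MR(t) = (M_t - M_e) / (M_0 - M_e)

decays from 1 toward 0, where ``M_0`` is the initial and ``M_e`` the
equilibrium moisture content.  The drying rate over a weighing interval
(t1, t2) is the moisture lost per unit time, reported as a positive
magnitude for a drying (decreasing) series.

Times are minutes throughout this module; the diffusivity module converts
to seconds internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateSeriesError, InvalidInputError

__all__ = [
    "MoistureSeries",
    "MRSeries",
    "DryingRateSeries",
    "EquilibriumResult",
    "detect_equilibrium",
    "compute_moisture_ratio",
    "compute_drying_rate",
]


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class MoistureSeries:
    """Timestamped dry-basis moisture measurements at one drying temperature.

    Parameters
    ----------
    times : array-like
        Minutes since drying start; strictly increasing, first value 0.
    moisture : array-like
        Dry-basis moisture content, kg H2O·kg⁻¹ db, one per time; all >= 0.
    temperature_C : float
        Drying air temperature, °C.
    thickness_m : float
        Slab (bed) thickness in metres; must be positive.
    label : str
        Free-text treatment identifier.
    """

    times: np.ndarray
    moisture: np.ndarray
    temperature_C: float
    thickness_m: float = 0.01
    label: str = ""

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        moisture = _as_float_array(self.moisture, "moisture")
        if len(times) != len(moisture):
            raise InvalidInputError("times and moisture must have equal length")
        if len(times) < 3:
            raise InvalidInputError("a moisture series needs at least 3 points")
        if times[0] != 0.0:
            raise InvalidInputError("times must start at 0 (minutes since start)")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(moisture < 0):
            raise InvalidInputError("moisture values must be non-negative")
        if self.thickness_m <= 0:
            raise InvalidInputError("thickness_m must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "moisture", moisture)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def m0(self) -> float:
        """Initial moisture content M_0 (first measurement)."""
        return float(self.moisture[0])


@dataclass(frozen=True)
class MRSeries:
    """Dimensionless moisture-ratio series at one temperature.

    ``mr[0]`` equals 1 exactly when built by :func:`compute_moisture_ratio`;
    series generated from the Fick slab closed form start at 8/π² instead,
    so the constructor only enforces non-negativity and alignment.
    """

    times: np.ndarray
    mr: np.ndarray
    temperature_C: float

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        mr = _as_float_array(self.mr, "mr")
        if len(times) != len(mr):
            raise InvalidInputError("times and mr must have equal length")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(mr < 0):
            raise InvalidInputError("moisture ratios must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "mr", mr)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class DryingRateSeries:
    """Per-interval drying rates, kg H2O·kg⁻¹ db·min⁻¹.

    ``rates[i]`` covers the interval between measurements i and i+1 and is
    associated with the interval midpoint ``midpoints[i]``.  Positive values
    mean moisture loss; negative values (rewetting) are preserved and
    flagged via ``has_negative``.
    """

    midpoints: np.ndarray
    rates: np.ndarray
    has_negative: bool


@dataclass(frozen=True)
class EquilibriumResult:
    """Outcome of the equilibrium-endpoint search."""

    index: int
    m_e: float
    converged: bool


def detect_equilibrium(
    series: MoistureSeries, rel_threshold: float = 1e-4
) -> EquilibriumResult:
    """Find the first measurement at which drying has equilibrated.

    Equilibrium is declared at the first index ``i >= 2`` such that the
    relative change between consecutive values is below ``rel_threshold``
    over three consecutive measurements (i.e. for both intervals
    ``(i-2, i-1)`` and ``(i-1, i)``).  The default threshold 1e-4
    corresponds to a weight change of less than 0.01%.

    The criterion is relative, so it is invariant under uniform rescaling
    of the moisture values.

    Returns
    -------
    EquilibriumResult
        ``index`` of the equilibrium measurement, the equilibrium moisture
        ``m_e`` at that index, and ``converged``.  If the criterion is
        never met, the last index is returned with ``converged=False``.
    """
    if rel_threshold <= 0:
        raise InvalidInputError("rel_threshold must be positive")
    m = series.moisture
    below = np.empty(len(m) - 1, dtype=bool)
    for j in range(1, len(m)):
        prev = abs(m[j - 1])
        diff = abs(m[j] - m[j - 1])
        below[j - 1] = (diff == 0.0) if prev == 0.0 else (diff / prev < rel_threshold)
    for i in range(2, len(m)):
        if below[i - 2] and below[i - 1]:
            return EquilibriumResult(index=i, m_e=float(m[i]), converged=True)
    return EquilibriumResult(index=len(m) - 1, m_e=float(m[-1]), converged=False)


def compute_moisture_ratio(series: MoistureSeries, m_e: float) -> MRSeries:
    """Convert a moisture series to the dimensionless moisture ratio.

    MR_i = (M_t,i − M_e) / (M_0 − M_e); the first value is exactly 1.

    Raises
    ------
    DegenerateSeriesError
        If M_0 equals M_e (zero denominator).
    """
    m0 = series.m0
    denom = m0 - m_e
    if denom == 0.0:
        raise DegenerateSeriesError("M_0 equals M_e; moisture ratio undefined")
    mr = (series.moisture - m_e) / denom
    mr = mr.copy()
    mr[0] = 1.0  # exact by definition
    return MRSeries(times=series.times, mr=mr, temperature_C=series.temperature_C)


def compute_drying_rate(series: MoistureSeries) -> DryingRateSeries:
    """Per-interval drying rate DR = (M_t1 − M_t2)/(t2 − t1).

    The denominator uses t2 − t1 so a drying (decreasing) series yields
    positive rates.  Rewetting steps give negative rates, preserved and
    flagged.
    """
    if len(series) < 2:  # unreachable through MoistureSeries, kept for rigor
        raise InvalidInputError("drying rate needs at least 2 points")
    dt = np.diff(series.times)
    dm = -np.diff(series.moisture)
    rates = dm / dt
    midpoints = series.times[:-1] + dt / 2.0
    return DryingRateSeries(
        midpoints=midpoints, rates=rates, has_negative=bool(np.any(rates < 0))
    )


def invert_moisture_ratio(mr: MRSeries, m0: float, m_e: float) -> np.ndarray:
    """Recover moisture values from a ratio series: M = MR·(M_0−M_e) + M_e."""
    return mr.mr * (m0 - m_e) + m_e
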