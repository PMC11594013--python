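"""Effective moisture diffusivity (Fick slab, slope method) and Arrhenius
activation energy.

For one-dimensional moisture transport in a slab, the first term of the
Fick-series solution gives

    MR(t) = (8/π²) · exp(−π² · D_cal · t / (4 L²))

with D_cal the calculated diffusivity (m²·s⁻¹) and L the half-thickness of
the sample (m).  Taking logarithms, ln(MR) is linear in time and D_cal
follows from the regression slope:

    D_cal = −slope · 4 L² / π²

The effective diffusivity corrects D_cal by a dimensionless geometric
factor R_g (13.1 for the flat-tray geometry used here):

    D_eff = D_cal / R_g

Temperature dependence follows the Arrhenius law

    D_eff = D_0 · exp(−E_a / (R · (T + 273.15)))

so the activation energy E_a (kJ·mol⁻¹) and pre-exponential factor D_0 come
from regressing ln(D_eff) on inverse absolute temperature.

Drying times are recorded in minutes; all regressions here are performed
in seconds so diffusivities are m²·s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import linregress

from .errors import InsufficientDataError, InvalidInputError
from .kinetics import MRSeries

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_GEOMETRIC_FACTOR",
    "DiffusivityEstimate",
    "ArrheniusResult",
    "simulate_fick_mr",
    "estimate_dcal",
    "correct_geometry",
    "fit_arrhenius",
]

GAS_CONSTANT = 8.314  # J·mol⁻¹·K⁻¹
DEFAULT_GEOMETRIC_FACTOR = 13.1  # flat-tray slab geometry
MR_FLOOR = 1e-4  # exclude the equilibrium plateau from the log-linear fit


@dataclass(frozen=True)
class DiffusivityEstimate:
    """Slope-method diffusivity at one temperature."""

    temperature_C: float
    slope: float            # per second, from ln(MR) vs t
    intercept: float
    r_squared_line: float
    d_cal: float            # m²·s⁻¹
    half_thickness_m: float
    n_points_used: int
    n_points_excluded: int
    r_g: float | None = None
    d_eff: float | None = None  # m²·s⁻¹, set by correct_geometry

    @property
    def positive_slope_warning(self) -> bool:
        """True when the regression slope is non-negative (non-drying data),
        which yields a non-positive diffusivity."""
        return self.slope >= 0


@dataclass(frozen=True)
class ArrheniusResult:
    """Arrhenius fit of effective diffusivity against temperature."""

    d_0: float              # pre-exponential factor, m²·s⁻¹
    e_a_kj_mol: float       # activation energy, kJ·mol⁻¹
    r_squared: float
    points: Tuple[Tuple[float, float], ...]  # (temperature_C, D_eff)


def simulate_fick_mr(
    d_cal: float, half_thickness_m: float, times_min: Sequence[float]
) -> np.ndarray:
    """First-term Fick slab solution MR(t) for a given D_cal and L.

    ``times_min`` are minutes (converted to seconds internally).
    """
    if d_cal <= 0:
        raise InvalidInputError("d_cal must be positive")
    if half_thickness_m <= 0:
        raise InvalidInputError("half_thickness_m must be positive")
    t_sec = np.asarray(times_min, dtype=float) * 60.0
    rate = math.pi**2 * d_cal / (4.0 * half_thickness_m**2)
    return (8.0 / math.pi**2) * np.exp(-rate * t_sec)


def estimate_dcal(
    mr: MRSeries, half_thickness_m: float, mr_floor: float = MR_FLOOR
) -> DiffusivityEstimate:
    """Slope-method diffusivity from the log-linear moisture-ratio decay.

    Ordinary least squares of ln(MR) on time in seconds, using points with
    MR above ``mr_floor`` (the t = 0 point is included; it lies on the
    line for data following the Fick closed form).  D_cal = −slope·4L²/π².

    Raises
    ------
    InsufficientDataError
        If fewer than 3 points survive the floor.
    """
    if half_thickness_m <= 0:
        raise InvalidInputError("half_thickness_m must be positive")
    usable = mr.mr > mr_floor
    n_used = int(np.sum(usable))
    if n_used < 3:
        raise InsufficientDataError(
            f"only {n_used} points with MR > {mr_floor}; need at least 3"
        )
    t_sec = mr.times[usable] * 60.0
    reg = linregress(t_sec, np.log(mr.mr[usable]))
    d_cal = -reg.slope * 4.0 * half_thickness_m**2 / math.pi**2
    return DiffusivityEstimate(
        temperature_C=mr.temperature_C,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared_line=float(reg.rvalue**2),
        d_cal=float(d_cal),
        half_thickness_m=half_thickness_m,
        n_points_used=n_used,
        n_points_excluded=len(mr) - n_used,
    )


def correct_geometry(
    estimate: DiffusivityEstimate | float, r_g: float = DEFAULT_GEOMETRIC_FACTOR
):
    """Apply the geometric correction D_eff = D_cal / R_g.

    Accepts either a :class:`DiffusivityEstimate` (returns a copy with
    ``d_eff`` and ``r_g`` filled in) or a bare D_cal (returns D_eff).
    """
    if r_g <= 0:
        raise InvalidInputError("geometric factor R_g must be positive")
    if isinstance(estimate, DiffusivityEstimate):
        return DiffusivityEstimate(
            temperature_C=estimate.temperature_C,
            slope=estimate.slope,
            intercept=estimate.intercept,
            r_squared_line=estimate.r_squared_line,
            d_cal=estimate.d_cal,
            half_thickness_m=estimate.half_thickness_m,
            n_points_used=estimate.n_points_used,
            n_points_excluded=estimate.n_points_excluded,
            r_g=r_g,
            d_eff=estimate.d_cal / r_g,
        )
    return float(estimate) / r_g


def fit_arrhenius(points: Sequence[Tuple[float, float]]) -> ArrheniusResult:
    """Activation energy and pre-exponential factor from (T °C, D_eff) pairs.

    Least squares of ln(D_eff) on 1/(T + 273.15); E_a = −slope·R reported
    in kJ·mol⁻¹, D_0 = exp(intercept).

    Raises
    ------
    InvalidInputError
        With fewer than 2 points or any non-positive D_eff.
    """
    pts = [(float(t), float(d)) for t, d in points]
    if len(pts) < 2:
        raise InvalidInputError("Arrhenius fit needs at least 2 points")
    if any(d <= 0 for _, d in pts):
        raise InvalidInputError("all D_eff values must be positive")
    inv_t = np.array([1.0 / (t + 273.15) for t, _ in pts])
    ln_d = np.log([d for _, d in pts])
    if np.allclose(ln_d, ln_d[0]):
        # temperature-independent diffusivity: flat line, E_a = 0
        return ArrheniusResult(
            d_0=float(np.exp(ln_d[0])), e_a_kj_mol=0.0, r_squared=1.0,
            points=tuple(pts),
        )
    reg = linregress(inv_t, ln_d)
    e_a = -reg.slope * GAS_CONSTANT / 1000.0  # J → kJ per mole
    return ArrheniusResult(
        d_0=float(np.exp(reg.intercept)),
        e_a_kj_mol=float(e_a),
        r_squared=float(reg.rvalue**2),
        points=tuple(pts),
    )
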