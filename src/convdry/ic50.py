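"""Percent inhibition and IC50 estimation for radical-scavenging assays.

DPPH/ABTS serial-dilution assays measure a control absorbance A_c and a
sample absorbance A_s per extract concentration.  Percent inhibition is,
by the standard scavenging convention,

    %inh = 100 · (A_c − A_s) / A_c

(an ``as_printed`` convention 100·A_s/A_c is available for compatibility
with sources that state the complement; the two conventions sum to 100).

The IC50 — the concentration giving 50 % inhibition — is estimated by a
four-parameter logistic (4PL) dose–response fit

    inh(c) = lower + (upper − lower) / (1 + (ic50 / c) ** hill)

with the asymptotes fixed at 0/100 by default, as appropriate for a
percent-inhibition scale.  The concentration axis is handled on a log
scale internally (serial dilutions are geometric), so the fit is invariant
under uniform rescaling of concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InsufficientDataError, InvalidInputError

__all__ = ["DoseResponseSeries", "IC50Estimate", "percent_inhibition", "fit_ic50"]


def percent_inhibition(
    a_control: float, a_sample: float, convention: str = "standard"
) -> float:
    """Percent inhibition from control and sample absorbances.

    convention="standard": 100·(A_c − A_s)/A_c (scavenging removes
    absorbance).  convention="as_printed": the complement 100·A_s/A_c.
    """
    if a_control <= 0:
        raise InvalidInputError("control absorbance must be positive")
    if convention == "standard":
        return 100.0 * (a_control - a_sample) / a_control
    if convention == "as_printed":
        return 100.0 * a_sample / a_control
    raise InvalidInputError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class DoseResponseSeries:
    """Concentration vs percent-inhibition pairs for one assay."""

    concentrations: np.ndarray  # mg·mL⁻¹, strictly increasing and positive
    inhibition_pct: np.ndarray  # percent, within [-5, 105] measurement slack
    assay: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        inh = np.asarray(self.inhibition_pct, dtype=float)
        if conc.ndim != 1 or conc.shape != inh.shape:
            raise InvalidInputError("concentrations and inhibition must be 1-D, equal length")
        if np.any(conc <= 0):
            raise InvalidInputError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise InvalidInputError("concentrations must be strictly increasing")
        if np.any((inh < -5.0) | (inh > 105.0)):
            raise InvalidInputError("inhibition must lie within [-5, 105] percent")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "inhibition_pct", inh)

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class IC50Estimate:
    """Fitted 4PL dose–response parameters."""

    ic50: float           # mg·mL⁻¹
    hill_slope: float
    lower: float
    upper: float
    r_squared: float
    extrapolated: bool    # True when the data never cross 50 % inhibition


def _logistic(conc: np.ndarray, lower: float, upper: float, log_ic50: float, hill: float):
    # (ic50/c)^hill computed in log space for conditioning
    return lower + (upper - lower) / (1.0 + np.exp(hill * (log_ic50 - np.log(conc))))


def fit_ic50(
    series: DoseResponseSeries,
    fix_asymptotes: bool = True,
    lower: float = 0.0,
    upper: float = 100.0,
    monotone_tol: float = 10.0,
) -> IC50Estimate:
    """Estimate the IC50 by least-squares 4PL regression.

    With ``fix_asymptotes`` (default) the lower/upper plateaus are held at
    0/100; otherwise they are fitted.  If the responses never cross 50 %
    the estimate is returned with ``extrapolated=True``.

    Raises
    ------
    InsufficientDataError
        With fewer than 4 concentrations.
    FitFailureError
        If the responses decrease with concentration by more than
        ``monotone_tol`` percentage points anywhere (non-monotone beyond
        noise tolerance).
    """
    if len(series) < 4:
        raise InsufficientDataError("IC50 fit needs at least 4 concentrations")
    conc = series.concentrations
    inh = series.inhibition_pct
    drops = np.diff(inh)
    if np.any(drops < -monotone_tol):
        raise FitFailureError(
            "inhibition decreases with concentration beyond noise tolerance"
        )
    extrapolated = not (inh.min() < 50.0 < inh.max())

    # initial log-IC50: interpolate the 50 % crossing, else mid-grid
    log_c = np.log(conc)
    if not extrapolated:
        idx = int(np.argmax(inh >= 50.0))
        if idx == 0:
            log_ic50_0 = log_c[0]
        else:
            f = (50.0 - inh[idx - 1]) / (inh[idx] - inh[idx - 1])
            log_ic50_0 = log_c[idx - 1] + f * (log_c[idx] - log_c[idx - 1])
    else:
        log_ic50_0 = float(log_c.mean())

    span = log_c[-1] - log_c[0]
    lo_log, hi_log = log_c[0] - 3 * span - 5, log_c[-1] + 3 * span + 5

    if fix_asymptotes:
        def residuals(x):
            return _logistic(conc, lower, upper, x[0], x[1]) - inh

        x0 = np.array([log_ic50_0, 1.0])
        bounds = ([lo_log, 0.05], [hi_log, 20.0])
    else:
        def residuals(x):
            return _logistic(conc, x[2], x[3], x[0], x[1]) - inh

        x0 = np.array([log_ic50_0, 1.0, float(inh.min()), float(inh.max())])
        bounds = (
            [lo_log, 0.05, -5.0, 40.0],
            [hi_log, 20.0, 60.0, 105.0],
        )

    sol = least_squares(residuals, x0, bounds=bounds, method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitFailureError("4PL optimizer failed to converge")

    fitted_lower = lower if fix_asymptotes else float(sol.x[2])
    fitted_upper = upper if fix_asymptotes else float(sol.x[3])
    pred = residuals(sol.x) + inh
    sse = float(np.sum((inh - pred) ** 2))
    tss = float(np.sum((inh - inh.mean()) ** 2))
    r_squared = 1.0 - sse / tss if tss > 0 else math.nan
    return IC50Estimate(
        ic50=float(np.exp(sol.x[0])),
        hill_slope=float(sol.x[1]),
        lower=fitted_lower,
        upper=fitted_upper,
        r_squared=r_squared,
        extrapolated=extrapolated,
    )


def standard_curve_interpolate(
    concentrations: Sequence[float], responses: Sequence[float], response: float
) -> float:
    """Linear standard-curve helper: concentration for a given response.

    Fits response = m·c + b by ordinary least squares and inverts it.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if len(conc) < 2:
        raise InsufficientDataError("standard curve needs at least 2 points")
    m, b = np.polyfit(conc, resp, 1)
    if m == 0:
        raise InvalidInputError("flat standard curve; cannot invert")
    return float((response - b) / m)
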