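"""Nonlinear least-squares fitting of thin-layer models and model ranking.

Constants are estimated by minimizing the sum of squared errors between
experimental and predicted moisture ratios with a bounded trust-region
least-squares solver, started from a heuristic initial point plus a
Latin-hypercube multi-start over the parameter bounds.  The multi-start is
seeded, so fits are deterministic for a given configuration.

Moisture-ratio series record time in minutes; thin-layer rate constants
are expressed per hour (see :mod:`convdry.models`), so times are converted
minutes -> hours before the curve is evaluated.  Fitted k values are
therefore h⁻ⁿ.

Each fit carries the seven-statistic battery used to compare candidate
models:

    R²    = 1 − SSE / Σ(MR_exp,i − mean(MR_exp))²
    χ²    = Σ (MR_exp,i − MR_pre,i)² / MR_pre,i      (guarded, see below)
    MSE   = SSE / N
    RMSE  = √MSE
    AIC   = N·ln(SSE/N) + 2K
    AICc  = AIC + 2K(K+1)/(N−K−1)

The χ² denominator is the predicted MR with no degrees-of-freedom divisor;
points with MR_pre below a small floor are excluded from the χ² sum (and
counted) to avoid division blow-ups on the equilibrium plateau.  Perfect
fits (SSE = 0) report AIC/AICc as −inf with a ``perfect_fit`` flag.

Ranking is ascending by AICc (the small-sample-corrected criterion), with
ties broken by RMSE and then by fewer parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress, qmc

from .errors import (
    DegenerateSeriesError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
)
from .kinetics import MRSeries
from .models import ThinLayerModel, evaluate_model, get_model

__all__ = ["FitStats", "FitResult", "FitOptions", "goodness_of_fit", "fit_model", "rank_models"]

CHI2_PRED_FLOOR = 1e-6


@dataclass(frozen=True)
class FitStats:
    """The seven-statistic goodness-of-fit battery."""

    r_squared: float
    chi_squared: float
    mse: float
    sse: float
    rmse: float
    aic: float
    aicc: float
    n_chi2_excluded: int = 0
    aicc_defined: bool = True
    perfect_fit: bool = False


@dataclass(frozen=True)
class FitResult:
    """Estimated constants and fit battery for one model on one MR series."""

    model_name: str
    params: Dict[str, float]
    n_obs: int
    n_params: int
    stats: FitStats
    converged: bool
    n_starts_used: int


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :func:`fit_model`.

    n_starts Latin-hypercube points are drawn over the model bounds and a
    heuristic start (log-linear slope for k, neutral values elsewhere) is
    always added.  sse_tol is the idempotence tolerance on SSE.
    """

    n_starts: int = 5
    seed: int = 0
    sse_tol: float = 1e-10


def goodness_of_fit(
    mr_exp: Sequence[float], mr_pre: Sequence[float], k_params: int
) -> FitStats:
    """Compute the seven-statistic battery for predicted vs experimental MR.

    Raises
    ------
    DegenerateSeriesError
        If the experimental series has zero total variance (R² undefined).
    """
    exp = np.asarray(mr_exp, dtype=float)
    pre = np.asarray(mr_pre, dtype=float)
    if exp.shape != pre.shape or exp.ndim != 1:
        raise InvalidInputError("mr_exp and mr_pre must be 1-D of equal length")
    n = len(exp)
    if n <= k_params:
        raise InsufficientDataError(
            f"need more than K={k_params} observations, got N={n}"
        )
    resid = exp - pre
    sse = float(np.sum(resid**2))
    tss = float(np.sum((exp - exp.mean()) ** 2))
    if tss == 0.0:
        raise DegenerateSeriesError("experimental MR series is constant; R² undefined")
    r_squared = 1.0 - sse / tss

    usable = pre > CHI2_PRED_FLOOR
    n_excluded = int(np.sum(~usable))
    chi_squared = float(np.sum(resid[usable] ** 2 / pre[usable]))

    mse = sse / n
    rmse = math.sqrt(mse)
    perfect = sse == 0.0
    if perfect:
        aic = -math.inf
    else:
        aic = n * math.log(sse / n) + 2 * k_params
    aicc_defined = n > k_params + 1
    if not aicc_defined:
        aicc = math.nan
    elif perfect:
        aicc = -math.inf
    else:
        aicc = aic + 2 * k_params * (k_params + 1) / (n - k_params - 1)
    return FitStats(
        r_squared=r_squared,
        chi_squared=chi_squared,
        mse=mse,
        sse=sse,
        rmse=rmse,
        aic=aic,
        aicc=aicc,
        n_chi2_excluded=n_excluded,
        aicc_defined=aicc_defined,
        perfect_fit=perfect,
    )


def _heuristic_start(model: ThinLayerModel, times: np.ndarray, mr: np.ndarray) -> np.ndarray:
    """A physically motivated initial point: k from the log-linear slope of
    ln(MR) vs t, a=1, n=1, b=0, c=0, all clipped inside the bounds."""
    positive = mr > 1e-8
    k0 = 0.01
    if np.sum(positive) >= 2:
        reg = linregress(times[positive], np.log(mr[positive]))
        if reg.slope < 0:
            k0 = -reg.slope
    defaults = {"k": k0, "n": 1.0, "a": 1.0, "b": 0.0, "c": 0.0}
    x0 = []
    for p in model.param_names:
        lo, hi = model.bounds[p]
        margin = 1e-9 * (hi - lo)
        x0.append(min(max(defaults[p], lo + margin), hi - margin))
    return np.asarray(x0)


def fit_model(
    mr: MRSeries, model: ThinLayerModel | str, options: FitOptions | None = None
) -> FitResult:
    """Fit one thin-layer model to a moisture-ratio series.

    Minimizes Σ(MR_exp − MR_pre)² over the model's bounds via multi-start
    bounded least squares.  Deterministic for a fixed ``options.seed``.

    Raises
    ------
    InsufficientDataError
        If fewer than K+2 observations are available.
    FitFailureError
        If no start converges; carries the best attempt.
    """
    if isinstance(model, str):
        model = get_model(model)
    opts = options or FitOptions()
    times = mr.times / 60.0  # minutes -> hours, the model time base
    y = mr.mr
    k = model.n_params
    if len(y) < k + 2:
        raise InsufficientDataError(
            f"model {model.name!r} needs at least {k + 2} observations, got {len(y)}"
        )
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("mr values must be finite")

    lo = np.array([model.bounds[p][0] for p in model.param_names])
    hi = np.array([model.bounds[p][1] for p in model.param_names])

    sampler = qmc.LatinHypercube(d=k, seed=opts.seed)
    starts = [_heuristic_start(model, times, y)]
    starts.extend(qmc.scale(sampler.random(opts.n_starts), lo, hi))

    def residuals(x: np.ndarray) -> np.ndarray:
        return model.func(times, *x) - y

    best = None
    best_sse = math.inf
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        sse = float(2 * sol.cost)
        if sol.success:
            any_success = True
        if sse < best_sse:
            best_sse = sse
            best = sol

    if best is None:
        raise FitFailureError(f"no start converged for model {model.name!r}")

    params = {p: float(v) for p, v in zip(model.param_names, best.x)}
    stats = goodness_of_fit(y, evaluate_model(model, params, times), k)
    result = FitResult(
        model_name=model.name,
        params=params,
        n_obs=len(y),
        n_params=k,
        stats=stats,
        converged=any_success,
        n_starts_used=len(starts),
    )
    if not any_success:
        raise FitFailureError(
            f"no start converged for model {model.name!r}", best_attempt=result
        )
    return result


def rank_models(fits: Sequence[FitResult]) -> List[FitResult]:
    """Order fits best-first: ascending AICc, ties by RMSE, then fewer params.

    All fits must have been computed on the same number of observations;
    AICc values are otherwise not comparable.
    """
    if len(fits) < 2:
        raise InvalidInputError("ranking needs at least 2 fits")
    n_set = {f.n_obs for f in fits}
    if len(n_set) != 1:
        raise InvalidInputError(
            f"fits computed on different numbers of observations: {sorted(n_set)}"
        )
    return sorted(fits, key=lambda f: (f.stats.aicc, f.stats.rmse, f.n_params))
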