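"""Registry of the five semi-empirical thin-layer drying models.

Each model predicts the moisture ratio MR as a function of drying time t.
The model time base is HOURS: published rate constants for fruit-pomace
convective drying at 50-90 °C fall in k ≈ 0.26-0.99 h⁻ⁿ, which together
with drying times of 210-810 min and equilibrium moisture ratios of
3.5e-3-1.54e-2 pins the unit (a per-minute k of that magnitude would dry
the bed within a single 30-min weighing interval).  ``evaluate_model``
itself is unit-agnostic — it evaluates the curve at whatever times you
pass — but the fitting and simulation layers convert recorded minutes to
hours at the boundary.

The five curves:

    page:            MR = exp(-k * t**n)
    modified_page:   MR = exp(-k * t)**n
    henderson_pabis: MR = a * exp(-k * t)
    logarithmic:     MR = a * exp(-k * t) + c
    midilli:         MR = a * exp(-k * t**n) + b * t

with constants a (initial-moisture scale), b (linear drift), c (offset),
k (rate constant, h⁻ⁿ) and n (curvature exponent).  Note the exact
identity modified_page(k, n) == exp(-n*k*t), i.e. a Page model with rate
n*k and exponent 1.

Default parameter bounds are wide enough to contain all constants reported
for fruit-pomace drying in the 50–90 °C range while keeping the nonlinear
fits well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError

__all__ = ["ThinLayerModel", "MODELS", "get_model", "list_models", "evaluate_model"]

# per-parameter bounds; k strictly positive
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "k": (1e-6, 50.0),
    "n": (0.1, 5.0),
    "a": (0.5, 1.5),
    "b": (-0.01, 0.01),
    "c": (-0.5, 0.5),
}


@dataclass(frozen=True)
class ThinLayerModel:
    """A named thin-layer drying model with an ordered parameter list."""

    name: str
    param_names: Tuple[str, ...]
    func: Callable[..., np.ndarray]

    @property
    def bounds(self) -> Dict[str, Tuple[float, float]]:
        return {p: DEFAULT_BOUNDS[p] for p in self.param_names}

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _page(t, k, n):
    return np.exp(-k * t**n)


def _modified_page(t, k, n):
    return np.exp(-k * t) ** n


def _henderson_pabis(t, a, k):
    return a * np.exp(-k * t)


def _logarithmic(t, a, k, c):
    return a * np.exp(-k * t) + c


def _midilli(t, a, k, n, b):
    return a * np.exp(-k * t**n) + b * t


MODELS: Dict[str, ThinLayerModel] = {
    m.name: m
    for m in (
        ThinLayerModel("page", ("k", "n"), _page),
        ThinLayerModel("modified_page", ("k", "n"), _modified_page),
        ThinLayerModel("henderson_pabis", ("a", "k"), _henderson_pabis),
        ThinLayerModel("logarithmic", ("a", "k", "c"), _logarithmic),
        ThinLayerModel("midilli", ("a", "k", "n", "b"), _midilli),
    )
}


def get_model(name: str) -> ThinLayerModel:
    """Look up a model spec by name (raises on unknown names)."""
    try:
        return MODELS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown model {name!r}; choose from {sorted(MODELS)}"
        ) from None


def list_models() -> Sequence[ThinLayerModel]:
    """All five registered model specs, in registry order."""
    return tuple(MODELS.values())


def evaluate_model(
    model: ThinLayerModel | str,
    params: Mapping[str, float],
    times: Sequence[float],
) -> np.ndarray:
    """Evaluate a model's predicted MR at the given times.

    Times are in the unit the parameters were expressed in (hours for the
    package's fitted constants).

    Raises
    ------
    InvalidInputError
        If a required parameter is missing or any time is negative.
    """
    if isinstance(model, str):
        model = get_model(model)
    missing = [p for p in model.param_names if p not in params]
    if missing:
        raise InvalidInputError(f"model {model.name!r} missing parameters {missing}")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("times must be non-negative")
    args = [float(params[p]) for p in model.param_names]
    return model.func(t, *args)
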