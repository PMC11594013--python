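"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the structure of a convective-drying study of fruit
pomace: monotone moisture-ratio decay at 50–90 °C sampled every 30 min
with analytical-balance noise, an equilibrium plateau that rises with
temperature, Arrhenius-distributed effective diffusivities, serial-dilution
inhibition curves, and replicated (n = 3) treatment-property tables.

Every generator takes an explicit seed and returns its ground truth
alongside the data, so parameter-recovery tests never re-enter the truth
by hand.  All randomness flows through ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .diffusivity import GAS_CONSTANT, simulate_fick_mr
from .errors import ConfigError, InvalidInputError
from .ic50 import DoseResponseSeries
from .compare import GroupTable
from .kinetics import MoistureSeries
from .models import evaluate_model, get_model

__all__ = [
    "SimulationConfig",
    "DryingTruth",
    "simulate_drying_experiment",
    "simulate_arrhenius_set",
    "simulate_dose_response",
    "simulate_property_table",
    "default_equilibrium_mr",
    "DEFAULT_DILUTION_GRID",
]

# Study protocol defaults: 30-min weighings out to 810 min, 0.01 m bed.
DEFAULT_TIME_END_MIN = 810.0
DEFAULT_TIME_STEP_MIN = 30.0
DEFAULT_THICKNESS_M = 0.01
DEFAULT_M0 = 4.0            # kg H2O·kg⁻¹ db, typical wet pomace
DEFAULT_ME = 0.05           # kg H2O·kg⁻¹ db
DEFAULT_NOISE_SD_MR = 0.005
BALANCE_RESOLUTION_G = 0.001

# Equilibrium moisture-ratio plateau observed to rise with temperature:
# 3.5e-3 at 50 °C up to 1.54e-2 at 90 °C (surface hardening retains moisture).
_EQ_MR_AT_50C = 3.5e-3
_EQ_MR_AT_90C = 1.54e-2


def default_equilibrium_mr(temperature_C: float) -> float:
    """Equilibrium MR floor, interpolated linearly in temperature over the
    50–90 °C study band and clamped to the observed range outside it."""
    frac = (temperature_C - 50.0) / 40.0
    frac = min(max(frac, 0.0), 1.0)
    return _EQ_MR_AT_50C + frac * (_EQ_MR_AT_90C - _EQ_MR_AT_50C)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for one synthetic drying experiment.

    kind selects the generating curve: a thin-layer model from the registry
    or the first-term Fick slab solution.  Noise is additive Gaussian on MR
    (default sd 0.005), optionally followed by quantization of the implied
    mass at the balance resolution (0.001 g).
    """

    kind: str = "thin_layer_model"          # or "fick_slab"
    model: str = "page"
    params: Mapping[str, float] = field(default_factory=lambda: {"k": 0.6635, "n": 1.0826})
    d_cal: float = 2.0e-9                   # m²·s⁻¹, used by fick_slab
    temperature_C: float = 70.0
    thickness_m: float = DEFAULT_THICKNESS_M
    time_end_min: float = DEFAULT_TIME_END_MIN
    time_step_min: float = DEFAULT_TIME_STEP_MIN
    m0: float = DEFAULT_M0
    m_e: float = DEFAULT_ME
    equilibrium_mr: Optional[float] = None  # None -> temperature default
    noise_sd_mr: float = DEFAULT_NOISE_SD_MR
    quantize_balance: bool = False
    dry_mass_g: float = 50.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("thin_layer_model", "fick_slab"):
            raise ConfigError(f"unknown generator kind {self.kind!r}")
        if self.noise_sd_mr < 0:
            raise ConfigError("noise_sd_mr must be non-negative")
        if self.time_end_min <= 0 or self.time_step_min <= 0:
            raise ConfigError("time grid must be positive")
        if self.m0 <= self.m_e:
            raise ConfigError("initial moisture must exceed equilibrium moisture")


@dataclass(frozen=True)
class DryingTruth:
    """Ground-truth record emitted next to each synthetic drying series."""

    kind: str
    model: str
    params: Dict[str, float]
    d_cal: float
    temperature_C: float
    m0: float
    m_e: float
    equilibrium_mr: float
    noise_sd_mr: float
    seed: int

    def as_dict(self) -> Dict[str, object]:
        d = {
            "kind": self.kind,
            "model": self.model,
            "d_cal": self.d_cal,
            "temperature_C": self.temperature_C,
            "m0": self.m0,
            "m_e": self.m_e,
            "equilibrium_mr": self.equilibrium_mr,
            "noise_sd_mr": self.noise_sd_mr,
            "seed": self.seed,
        }
        for k, v in self.params.items():
            d[f"param_{k}"] = v
        return d


def simulate_drying_experiment(
    config: SimulationConfig,
) -> Tuple[MoistureSeries, DryingTruth]:
    """Generate a synthetic moisture series plus its ground truth.

    The MR curve is generated from the configured model (or Fick slab),
    clipped below at the equilibrium MR floor, converted to dry-basis
    moisture with the configured M_0/M_e, and perturbed with additive
    Gaussian noise on MR.  Noise large enough to drive MR below −0.1 is a
    configuration error; small negative excursions are clipped to 0.
    """
    times = np.arange(0.0, config.time_end_min + 1e-9, config.time_step_min)
    eq_mr = (
        config.equilibrium_mr
        if config.equilibrium_mr is not None
        else default_equilibrium_mr(config.temperature_C)
    )
    if config.kind == "thin_layer_model":
        model = get_model(config.model)
        # rate constants are per hour; the weighing grid is in minutes
        mr = evaluate_model(model, dict(config.params), times / 60.0)
        params = {p: float(config.params[p]) for p in model.param_names}
    else:
        half = config.thickness_m / 2.0
        mr = simulate_fick_mr(config.d_cal, half, times)
        params = {}
    mr = np.maximum(mr, eq_mr)

    rng = np.random.default_rng(config.seed)
    if config.noise_sd_mr > 0:
        mr = mr + rng.normal(0.0, config.noise_sd_mr, size=mr.shape)
        if mr.min() < -0.1:
            raise ConfigError(
                "noise drove MR below -0.1; reduce noise_sd_mr or raise the floor"
            )
        mr = np.maximum(mr, 0.0)
        mr[0] = 1.0 if config.kind == "thin_layer_model" else mr[0]

    moisture = mr * (config.m0 - config.m_e) + config.m_e
    if config.quantize_balance:
        # quantize the implied sample mass at the balance resolution
        mass_g = config.dry_mass_g * (1.0 + moisture)
        mass_g = np.round(mass_g / BALANCE_RESOLUTION_G) * BALANCE_RESOLUTION_G
        moisture = mass_g / config.dry_mass_g - 1.0
    moisture = np.maximum(moisture, 0.0)

    series = MoistureSeries(
        times=times,
        moisture=moisture,
        temperature_C=config.temperature_C,
        thickness_m=config.thickness_m,
        label=config.label or f"synthetic_{config.temperature_C:g}C",
    )
    truth = DryingTruth(
        kind=config.kind,
        model=config.model if config.kind == "thin_layer_model" else "",
        params=params,
        d_cal=config.d_cal if config.kind == "fick_slab" else float("nan"),
        temperature_C=config.temperature_C,
        m0=config.m0,
        m_e=config.m_e,
        equilibrium_mr=eq_mr,
        noise_sd_mr=config.noise_sd_mr,
        seed=config.seed,
    )
    return series, truth


def simulate_arrhenius_set(
    d_0: float,
    e_a_kj_mol: float,
    temperatures_C: Sequence[float] = (50.0, 60.0, 70.0, 80.0, 90.0),
    noise_sd_log_d: float = 0.0,
    seed: int = 0,
) -> List[Tuple[float, float]]:
    """(temperature, D_eff) pairs from the Arrhenius law with lognormal noise.

    D_eff(T) = D_0·exp(−E_a/(R·(T+273.15))) with E_a in kJ·mol⁻¹; noise is
    Gaussian on ln(D_eff) with sd ``noise_sd_log_d``.
    """
    if d_0 <= 0:
        raise InvalidInputError("d_0 must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures_C:
        ln_d = np.log(d_0) - e_a_kj_mol * 1000.0 / (GAS_CONSTANT * (t + 273.15))
        if noise_sd_log_d > 0:
            ln_d += rng.normal(0.0, noise_sd_log_d)
        out.append((float(t), float(np.exp(ln_d))))
    return out


def _twofold_dilutions(top: float, n: int) -> np.ndarray:
    grid = top / 2.0 ** np.arange(n)
    return np.sort(grid)


# 8 two-fold dilutions from 0.13 mg·mL⁻¹ — the standard-curve window
# (≈0.001–0.13 mg·mL⁻¹) used for antioxidant serial dilutions.
DEFAULT_DILUTION_GRID: np.ndarray = _twofold_dilutions(0.13, 8)


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    concentrations: Optional[Sequence[float]] = None,
    noise_sd_pct: float = 0.0,
    seed: int = 0,
    assay: str = "DPPH",
) -> DoseResponseSeries:
    """Logistic percent-inhibition curve with optional Gaussian noise.

    inhibition(c) = 100 / (1 + (ic50/c)^hill); noisy values are clipped to
    the measurement-slack window [−5, 105].
    """
    if ic50 <= 0:
        raise InvalidInputError("ic50 must be positive")
    conc = (
        np.sort(np.asarray(concentrations, dtype=float))
        if concentrations is not None
        else DEFAULT_DILUTION_GRID.copy()
    )
    inh = 100.0 / (1.0 + (ic50 / conc) ** hill)
    if noise_sd_pct > 0:
        rng = np.random.default_rng(seed)
        inh = inh + rng.normal(0.0, noise_sd_pct, size=inh.shape)
    inh = np.clip(inh, -5.0, 105.0)
    return DoseResponseSeries(concentrations=conc, inhibition_pct=inh, assay=assay)


def simulate_property_table(
    means: Mapping[str, float],
    sds: Mapping[str, float],
    n_replicates: int = 3,
    seed: int = 0,
    property_name: str = "",
    units: str = "",
) -> GroupTable:
    """Regenerate pseudo-replicates from printed mean ± SD summaries.

    Draws ``n_replicates`` normal values per treatment, seeded.  This is an
    approximate stand-in for unavailable replicate-level data: real assay
    replicates need not be normal and printed SDs are rounded.
    """
    if set(means) != set(sds):
        raise ConfigError("means and sds must cover the same treatments")
    if n_replicates < 2:
        raise ConfigError("need at least 2 replicates per treatment")
    if any(s < 0 for s in sds.values()):
        raise ConfigError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    groups = {
        label: rng.normal(means[label], sds[label], size=n_replicates)
        for label in means
    }
    return GroupTable(groups=groups, property_name=property_name, units=units)
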