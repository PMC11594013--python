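"""Delimited-text readers and report writers.

All inputs are headered CSV (decimal point ``.``):

* moisture series: ``time_min, moisture_db`` or ``time_min, mass_g`` (the
  latter needs a bone-dry mass to convert to dry-basis moisture);
* moisture-ratio series: ``time_min, mr``;
* Arrhenius table: ``temperature_C, deff_m2s``;
* dose–response: ``concentration_mg_ml, inhibition_pct`` or
  ``concentration_mg_ml, a_control, a_sample``;
* property table (long format): ``property, treatment, replicate, value``.

Report numbers are written at 4 significant figures.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .compare import GroupTable
from .errors import InvalidInputError
from .fitting import FitResult
from .ic50 import DoseResponseSeries, percent_inhibition
from .kinetics import MoistureSeries, MRSeries

__all__ = [
    "read_moisture_series",
    "read_mr_series",
    "read_arrhenius_table",
    "read_dose_response",
    "read_property_long",
    "write_moisture_series",
    "write_truth_sidecar",
    "fit_report_frame",
    "format_significant",
]


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise InvalidInputError(f"could not parse {path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    return df


def _require(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {missing}")


def read_moisture_series(
    path,
    temperature_C: float,
    thickness_m: float = 0.01,
    bone_dry_mass_g: Optional[float] = None,
    label: str = "",
) -> MoistureSeries:
    """Read a drying series from ``time_min, moisture_db`` (or
    ``time_min, mass_g`` with a bone-dry mass for the conversion
    M = (mass − mass_dry)/mass_dry)."""
    df = _read_csv(path)
    _require(df, ["time_min"], path)
    if "moisture_db" in df.columns:
        moisture = df["moisture_db"].to_numpy(dtype=float)
    elif "mass_g" in df.columns:
        if bone_dry_mass_g is None or bone_dry_mass_g <= 0:
            raise InvalidInputError(
                f"{path}: mass_g input needs a positive bone_dry_mass_g"
            )
        moisture = (df["mass_g"].to_numpy(dtype=float) - bone_dry_mass_g) / bone_dry_mass_g
    else:
        raise InvalidInputError(f"{path}: need a moisture_db or mass_g column")
    return MoistureSeries(
        times=df["time_min"].to_numpy(dtype=float),
        moisture=moisture,
        temperature_C=temperature_C,
        thickness_m=thickness_m,
        label=label or str(path),
    )


def read_mr_series(path, temperature_C: float) -> MRSeries:
    df = _read_csv(path)
    _require(df, ["time_min", "mr"], path)
    return MRSeries(
        times=df["time_min"].to_numpy(dtype=float),
        mr=df["mr"].to_numpy(dtype=float),
        temperature_C=temperature_C,
    )


def read_arrhenius_table(path) -> List[tuple]:
    df = _read_csv(path)
    _require(df, ["temperature_C", "deff_m2s"], path)
    return list(
        zip(df["temperature_C"].astype(float), df["deff_m2s"].astype(float))
    )


def read_dose_response(path, assay: str = "") -> DoseResponseSeries:
    df = _read_csv(path)
    _require(df, ["concentration_mg_ml"], path)
    df = df.sort_values("concentration_mg_ml")
    conc = df["concentration_mg_ml"].to_numpy(dtype=float)
    if "inhibition_pct" in df.columns:
        inh = df["inhibition_pct"].to_numpy(dtype=float)
    elif {"a_control", "a_sample"} <= set(df.columns):
        inh = np.array(
            [
                percent_inhibition(ac, as_)
                for ac, as_ in zip(df["a_control"], df["a_sample"])
            ]
        )
    else:
        raise InvalidInputError(
            f"{path}: need inhibition_pct or a_control/a_sample columns"
        )
    return DoseResponseSeries(concentrations=conc, inhibition_pct=inh, assay=assay)


def read_property_long(path) -> Dict[str, GroupTable]:
    """Long-format property table -> one GroupTable per property."""
    df = _read_csv(path)
    _require(df, ["property", "treatment", "value"], path)
    tables = {}
    for prop, sub in df.groupby("property", sort=False):
        groups = {
            str(tr): g["value"].to_numpy(dtype=float)
            for tr, g in sub.groupby("treatment", sort=False)
        }
        tables[str(prop)] = GroupTable(groups=groups, property_name=str(prop))
    return tables


def write_moisture_series(series: MoistureSeries, path) -> None:
    pd.DataFrame(
        {"time_min": series.times, "moisture_db": series.moisture}
    ).to_csv(path, index=False)


def write_truth_sidecar(truth_dict: Dict[str, object], path) -> None:
    """Key-value text sidecar recording a generator's ground truth."""
    with open(path, "w") as fh:
        for key, value in truth_dict.items():
            fh.write(f"{key} = {value}\n")


def format_significant(x: float, sig: int = 4) -> str:
    """Format a number at ``sig`` significant figures for reports."""
    if x == 0 or not np.isfinite(x):
        return str(x)
    return f"{x:.{sig}g}"


def fit_report_frame(fits_by_temperature: Dict[float, Iterable[FitResult]]) -> pd.DataFrame:
    """Tabular fit report: one row per (model, temperature) with constants
    and the seven-statistic battery, column units in headers."""
    rows = []
    for temp, fits in fits_by_temperature.items():
        for f in fits:
            row = {
                "model": f.model_name,
                "temperature_C": temp,
                "n_obs": f.n_obs,
                "n_params": f.n_params,
            }
            for p in ("a", "b", "c", "k", "n"):
                row[p] = f.params.get(p, float("nan"))
            s = f.stats
            row.update(
                r_squared=s.r_squared, chi_squared=s.chi_squared, mse=s.mse,
                sse=s.sse, rmse=s.rmse, aic=s.aic, aicc=s.aicc,
                converged=f.converged,
            )
            rows.append(row)
    return pd.DataFrame(rows)
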