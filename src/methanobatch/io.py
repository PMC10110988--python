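"""File I/O and the unit boundary.

Configs, observation CSVs and reports use the presentation units of the
laboratory (mBar, degC, ml, cells/ml); everything inside the package is
strict SI.  CSVs are comma-separated, UTF-8, "." decimal, with a header
row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult, ObservationSeries
from .reactor_model import (
    COMPONENTS,
    HenryEntry,
    LagPhase,
    MassTransfer,
    ReactorGeometry,
    SpeciesKinetics,
)
from .simulation import Event, Scenario, Trajectory

__all__ = [
    "MBAR_TO_PA",
    "mbar_to_pa",
    "pa_to_mbar",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "trajectory_frame",
    "write_trajectory_csv",
    "write_observations_csv",
    "read_observations_csv",
    "write_calibration_report",
    "load_scenario_yaml",
    "provenance_block",
]

MBAR_TO_PA = 100.0


def mbar_to_pa(p: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    return p * MBAR_TO_PA


def pa_to_mbar(p: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    return p / MBAR_TO_PA


def celsius_to_kelvin(t: float) -> float:
    return t + 273.15


def kelvin_to_celsius(t: float) -> float:
    return t - 273.15


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Trajectory as a tidy table with both Pa and mBar pressure columns."""
    data = {
        "time_s": traj.times,
        "pressure_Pa": traj.pressures,
        "pressure_mbar": pa_to_mbar(traj.pressures),
    }
    for i, c in enumerate(COMPONENTS):
        data[f"N_gas_{c}"] = [s.N_gas[i] for s in traj.states]
    for i, c in enumerate(COMPONENTS):
        data[f"N_liq_{c}"] = [s.N_liq[i] for s in traj.states]
    data["cells_total"] = [s.X for s in traj.states]
    data["cells_per_ml"] = traj.cell_densities
    return pd.DataFrame(data)


def write_trajectory_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    trajectory_frame(traj).to_csv(path, index=False)


def write_observations_csv(obs: ObservationSeries, path: Union[str, Path]) -> None:
    """Observation CSV: time_s, pressure_mbar and (sparse) cells_per_ml.

    Cell counts usually fall on pressure-sample times; rows holding only a
    cell count leave the pressure field empty.
    """
    df = pd.DataFrame(
        {"time_s": obs.times, "pressure_mbar": pa_to_mbar(obs.pressures)}
    )
    if obs.has_cells:
        cells = pd.DataFrame(
            {"time_s": obs.cell_times, "cells_per_ml": obs.cell_densities}
        )
        df = df.merge(cells, on="time_s", how="outer").sort_values("time_s")
    df.to_csv(path, index=False)


def read_observations_csv(
    path: Union[str, Path],
    pressure_sigma_mbar: float = 5.0,
    cell_sigma_log10: float = 0.3,
) -> ObservationSeries:
    """Read an observation CSV back into SI units.

    The measurement sigmas are metadata, not columns; supply them here.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"observation file {path} is empty")
    pmask = df["pressure_mbar"].notna()
    kwargs = {}
    if "cells_per_ml" in df.columns:
        cmask = df["cells_per_ml"].notna()
        if cmask.any():
            kwargs = {
                "cell_times": df.loc[cmask, "time_s"].to_numpy(),
                "cell_densities": df.loc[cmask, "cells_per_ml"].to_numpy(),
            }
    return ObservationSeries(
        times=df.loc[pmask, "time_s"].to_numpy(),
        pressures=mbar_to_pa(df.loc[pmask, "pressure_mbar"].to_numpy()),
        pressure_sigma=mbar_to_pa(pressure_sigma_mbar),
        cell_sigma_log10=cell_sigma_log10,
        **kwargs,
    )


def write_calibration_report(
    result: CalibrationResult,
    path: Union[str, Path],
    extra: Optional[dict] = None,
) -> None:
    """JSON report: fitted values, per-start spread, uniqueness flag."""
    payload = {
        "fitted": result.fitted,
        "objective_value": result.objective_value,
        "n_observations": result.n_obs,
        "uniqueness_flag": result.uniqueness_flag,
        "starts": [
            {k: v for k, v in s.items() if k != "residuals"} for s in result.starts
        ],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def load_scenario_yaml(path: Union[str, Path]) -> Scenario:
    """Build a scenario from a YAML config in presentation units.

    Expected layout (ml / mBar / degC / cells/ml at the boundary)::

        name: my_run
        geometry: {total_volume_ml: 132.5, liquid_volume_ml: 47.0,
                   contact_area_mm2: 1963.4}
        temperature_C: 65.0
        initial_pressure_mbar: 600.0
        feed_fractions: {H2: 0.8, CO2: 0.2}
        duration_s: 150000
        initial_cell_density_per_ml: 1.43e7
        kinetics: {mu_max: 1.7e-4, K_H2: 0.02, K_CO2: 0.011,
                   decay_b: 3.0e-7, yield_Y_H2: 4.1e12,
                   t_L_s: 7200, t_E_s: 36000}
        mass_transfer: {k_gw: 8.0e-2}
        henry:
          H2: {H_ref: 8.58e-6, T_ref_C: 65.0, vant_hoff_C: 500}
          ...
        events:                      # optional
          - {time_s: 700000, kind: refill, target_pressure_mbar: 1000}
    """
    cfg = yaml.safe_load(Path(path).read_text())
    try:
        g = cfg["geometry"]
        geometry = ReactorGeometry(
            total_volume=g["total_volume_ml"] * 1e-6,
            liquid_volume=g["liquid_volume_ml"] * 1e-6,
            gas_liquid_contact_area=g["contact_area_mm2"] * 1e-6,
        )
        kc = cfg["kinetics"]
        kinetics = SpeciesKinetics(
            mu_max=float(kc["mu_max"]),
            K_H2=float(kc["K_H2"]),
            K_CO2=float(kc["K_CO2"]),
            decay_b=float(kc["decay_b"]),
            yield_Y_H2=float(kc["yield_Y_H2"]),
            lag=LagPhase(float(kc.get("t_L_s", 0.0)), float(kc.get("t_E_s", 0.0))),
        )
        henry = {
            comp: HenryEntry(
                component=comp,
                H_ref=float(h["H_ref"]),
                T_ref=celsius_to_kelvin(float(h["T_ref_C"])),
                vant_hoff_C=float(h.get("vant_hoff_C", 0.0)),
            )
            for comp, h in cfg["henry"].items()
        }
        events = tuple(
            Event(
                time=float(e["time_s"]),
                kind=e["kind"],
                refill_target_pressure=(
                    mbar_to_pa(float(e["target_pressure_mbar"]))
                    if "target_pressure_mbar" in e
                    else None
                ),
                sample_volume=(
                    float(e["sample_volume_ml"]) * 1e-6
                    if "sample_volume_ml" in e
                    else None
                ),
            )
            for e in cfg.get("events", [])
        )
        return Scenario(
            name=cfg.get("name", Path(path).stem),
            geometry=geometry,
            temperature=celsius_to_kelvin(float(cfg["temperature_C"])),
            initial_pressure=mbar_to_pa(float(cfg["initial_pressure_mbar"])),
            feed_fractions={k: float(v) for k, v in cfg["feed_fractions"].items()},
            kinetics=kinetics,
            mass_transfer=MassTransfer(k_gw=float(cfg["mass_transfer"]["k_gw"])),
            henry_table=henry,
            initial_cell_density=float(cfg["initial_cell_density_per_ml"]),
            duration=float(cfg["duration_s"]),
            events=events,
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed scenario config {path}: {exc}") from exc


def provenance_block(seed: Optional[int] = None, config: Optional[dict] = None) -> dict:
    """Machine-readable provenance for run outputs."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    return {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest() if blob else None,
    }
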