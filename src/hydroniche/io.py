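"""Delimited-text readers/writers and the structured run configuration.

All tabular interchange is UTF-8 comma-separated text with a header row so
every artifact diffs cleanly; the injection-depth column uses the literal
``control`` to mark control samples.  The (depth x day) uptake grid is
written as a wide CSV (rows: dates; columns: cell-center depths in cm).
Configuration is YAML with explicit physical blocks (soil, canopy, feddes,
solver, site) carrying units in their key names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .isotope import CONTROL_LABEL, REQUIRED_COLUMNS
from .soilwater import (
    CanopyParams,
    FeddesParams,
    SiteConfig,
    SolverConfig,
    UptakeField,
    VanGenuchtenParams,
)

__all__ = [
    "read_samples",
    "write_samples",
    "read_weather",
    "write_weather",
    "write_profiles",
    "read_profiles",
    "write_uptake_field",
    "read_uptake_field",
    "validate_samples",
    "validate_weather",
    "load_config",
    "dump_config",
    "build_run_settings",
]

WEATHER_COLUMNS = [
    "date",
    "precip_cm",
    "tmin_C",
    "tmax_C",
    "rh_mean_pct",
    "wind_m_s",
    "solar_MJ_m2",
]


class ValidationError(ValueError):
    """Schema violation with a per-field report."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


# ---------------------------------------------------------------------------
# sample tables


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"injection_depth_cm": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing columns: {missing}"])
    return df


def validate_samples(samples: pd.DataFrame, depth_set=None) -> list[str]:
    """Return a list of per-row problems (empty when the table is valid)."""
    problems = []
    missing = [c for c in REQUIRED_COLUMNS if c not in samples.columns]
    if missing:
        return [f"missing columns: {missing}"]
    depth_col = samples["injection_depth_cm"].astype(str).str.strip()
    for i, value in depth_col.items():
        if value.lower() == CONTROL_LABEL:
            continue
        try:
            depth = float(value)
        except ValueError:
            problems.append(f"row {i}: injection depth {value!r} is not numeric")
            continue
        if depth < 0:
            problems.append(f"row {i}: negative injection depth {depth}")
        elif depth_set is not None and depth not in {float(d) for d in depth_set}:
            problems.append(
                f"row {i}: depth {depth:g} cm outside the campaign depth set "
                f"{sorted(float(d) for d in depth_set)}"
            )
    has_water = samples[["d2H_permil", "d18O_permil"]].notna().all(axis=1)
    has_n = (
        samples["d15N_permil"].notna()
        if "d15N_permil" in samples
        else pd.Series(False, index=samples.index)
    )
    for i in samples.index[~(has_water ^ has_n)]:
        problems.append(
            f"row {i}: exactly one tracer channel (water or nitrogen) "
            "must be populated"
        )
    gf_bad = ~samples["growth_form"].isin(["tree", "grass"])
    for i in samples.index[gf_bad]:
        problems.append(f"row {i}: unknown growth form {samples.at[i, 'growth_form']!r}")
    return problems


# ---------------------------------------------------------------------------
# weather tables


def write_weather(weather: pd.DataFrame, path) -> None:
    weather.to_csv(path, index=False)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    problems = validate_weather(df)
    if problems:
        raise ValidationError(problems)
    return df


def validate_weather(weather: pd.DataFrame) -> list[str]:
    problems = []
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        return [f"missing columns: {missing}"]
    if (weather["precip_cm"] < 0).any():
        problems.append("negative precipitation")
    if (weather["tmax_C"] < weather["tmin_C"]).any():
        problems.append("tmax below tmin")
    if ((weather["rh_mean_pct"] < 0) | (weather["rh_mean_pct"] > 100)).any():
        problems.append("relative humidity outside [0, 100]")
    return problems


# ---------------------------------------------------------------------------
# profiles and uptake grids


def write_profiles(frames, path) -> None:
    """Write per-(campaign, group, depth) proportion rows to CSV."""
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_uptake_field(field: UptakeField, path) -> None:
    field.as_frame().to_csv(path)


def read_uptake_field(path) -> pd.DataFrame:
    """Wide uptake grid back as a DataFrame (dates x depth columns)."""
    return pd.read_csv(path, index_col=0, parse_dates=True)


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG = {
    "seed": 0,
    "niche_mode": "per_season_depth",
    "bottom_bc": "free_drainage",
    "initial_head_cm": -300.0,
    "soil": {
        "theta_r": 0.089,
        "theta_s": 0.43,
        "alpha_per_cm": 0.01,
        "n": 1.23,
        "Ks_cm_per_day": 6.2,
        "l": 0.5,
    },
    "feddes": {"h1_cm": -10.0, "h2_cm": -25.0, "h3_cm": -200.0, "h4_cm": -8000.0},
    "canopy": {
        "height_cm": 60.0,
        "lai_per_cm": 0.024,
        "k_ext": 0.463,
        "interception_a_cm": 0.025,
    },
    "site": {"latitude_deg": -25.2, "elevation_m": 191.0, "albedo": 0.23},
    "solver": {
        "dz_cm": 1.0,
        "n_cells": 125,
        "dt_init_days": 0.02,
        "dt_min_days": 1.0e-6,
        "dt_max_days": 0.2,
        "max_iter": 60,
    },
}


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def build_run_settings(cfg: dict) -> dict:
    """Turn a config dict into the parameter objects the pipeline takes."""
    soil_cfg = cfg["soil"]
    soil = VanGenuchtenParams(
        theta_r=soil_cfg["theta_r"],
        theta_s=soil_cfg["theta_s"],
        alpha=soil_cfg["alpha_per_cm"],
        n=soil_cfg["n"],
        Ks=soil_cfg["Ks_cm_per_day"],
        l=soil_cfg.get("l", 0.5),
    )
    fd = cfg["feddes"]
    feddes = FeddesParams(fd["h1_cm"], fd["h2_cm"], fd["h3_cm"], fd["h4_cm"])
    cp = cfg["canopy"]
    canopy = CanopyParams(
        height_cm=cp["height_cm"],
        lai_per_cm=cp["lai_per_cm"],
        k_ext=cp["k_ext"],
        interception_a=cp["interception_a_cm"],
    )
    st = cfg["site"]
    site = SiteConfig(
        latitude_deg=st["latitude_deg"],
        elevation_m=st["elevation_m"],
        albedo=st.get("albedo", 0.23),
    )
    sv = cfg["solver"]
    solver = SolverConfig(
        dz=sv["dz_cm"],
        n_cells=sv["n_cells"],
        dt_init=sv["dt_init_days"],
        dt_min=sv["dt_min_days"],
        dt_max=sv["dt_max_days"],
        max_iter=sv["max_iter"],
    )
    return {
        "soil": soil,
        "feddes": feddes,
        "canopy": canopy,
        "site": site,
        "solver": solver,
        "niche_mode": cfg["niche_mode"],
        "initial_head_cm": cfg["initial_head_cm"],
        "bottom_bc": cfg["bottom_bc"],
    }


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
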