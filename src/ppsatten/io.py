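"""Tabular file formats and run configuration.

All files are plain comma-separated text with mandatory headers.  Values
are stored as fractions (never percent) and angles in degrees, machine
convention: 0° is the beam from above, increasing clockwise as seen from
the foot end of the bore.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .grid import (
    DEFAULT_FORBIDDEN,
    DEFAULT_WINDOW_LEFT,
    DEFAULT_WINDOW_RIGHT,
    GantryGrid,
    build_default_grid,
)
from .series import CONFIGURATIONS, AngularReadingSeries, AttenuationCurve, CurveRole, TransmissionCurve

log = logging.getLogger("ppsatten")

MEASUREMENT_COLUMNS = [
    "site", "configuration", "gantry_angle_deg", "raw_reading",
    "temperature_C", "pressure_hPa", "acquisition_index", "session_id",
]


def write_measurement_table(series_list, path) -> None:
    """Write one or more reading series as the standard measurement table."""
    if isinstance(series_list, AngularReadingSeries):
        series_list = [series_list]
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "site": s.site, "configuration": s.configuration,
            "gantry_angle_deg": s.angles, "raw_reading": s.readings,
            "temperature_C": s.temperature_c, "pressure_hPa": s.pressure_hpa,
            "acquisition_index": s.acquisition_index, "session_id": s.session_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")


def read_measurement_table(path) -> dict:
    """Read a measurement table, grouped by (site, session, configuration).

    Duplicate (session, angle) rows are averaged with a logged warning;
    malformed rows raise with the offending line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    numeric = {}
    for col in ("gantry_angle_deg", "raw_reading", "temperature_C",
                "pressure_hPa", "acquisition_index"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ValueError(
                f"{path}: line {bad[0] + 2}: cannot parse {col!r} "
                f"value {df[col].iloc[bad[0]]!r}"
            )
        numeric[col] = vals.to_numpy()
    angles = numeric["gantry_angle_deg"]
    if np.any((angles < 0) | (angles >= 360)):
        line = int(np.flatnonzero((angles < 0) | (angles >= 360))[0]) + 2
        raise ValueError(f"{path}: line {line}: gantry angle outside [0, 360)")
    if np.any(numeric["raw_reading"] <= 0):
        line = int(np.flatnonzero(numeric["raw_reading"] <= 0)[0]) + 2
        raise ValueError(f"{path}: line {line}: non-positive reading")
    bad_cfg = ~df["configuration"].isin(CONFIGURATIONS)
    if bad_cfg.any():
        line = int(np.flatnonzero(bad_cfg.to_numpy())[0]) + 2
        raise ValueError(
            f"{path}: line {line}: unknown configuration "
            f"{df['configuration'].iloc[np.flatnonzero(bad_cfg.to_numpy())[0]]!r}"
        )

    work = df[["site", "configuration", "session_id"]].copy()
    for col, vals in numeric.items():
        work[col] = vals

    out = {}
    for (site, session, cfg), group in work.groupby(
            ["site", "session_id", "configuration"], sort=False):
        dup = group.duplicated("gantry_angle_deg", keep=False)
        if dup.any():
            dup_angles = sorted(set(group.loc[dup, "gantry_angle_deg"]))
            log.warning("%s: duplicate readings at angles %s in session %s "
                        "averaged", path.name, dup_angles, session)
            group = (group.groupby("gantry_angle_deg", as_index=False, sort=False)
                     .mean(numeric_only=True))
        out[(site, session, cfg)] = AngularReadingSeries(
            angles=group["gantry_angle_deg"].to_numpy(),
            readings=group["raw_reading"].to_numpy(),
            temperature_c=group["temperature_C"].to_numpy(),
            pressure_hpa=group["pressure_hPa"].to_numpy(),
            acquisition_index=group["acquisition_index"].to_numpy().astype(int),
            site=site, session_id=session, configuration=cfg,
        )
    return out


def write_curve(curve, path, value_name: str | None = None) -> None:
    """Write a transmission or attenuation curve as (angle, value) CSV."""
    if value_name is None:
        value_name = ("attenuation" if isinstance(curve, AttenuationCurve)
                      else "transmission")
    data = {"gantry_angle_deg": curve.angles, value_name: curve.values}
    if isinstance(curve, AttenuationCurve) and curve.uncertainty is not None:
        data["uncertainty_1sd"] = curve.uncertainty
    if isinstance(curve, TransmissionCurve):
        data["role"] = curve.role.value
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def _grid_from_angles(angles: np.ndarray) -> GantryGrid:
    return GantryGrid(angles=angles, forbidden=frozenset())


def read_transmission_curve(path, role: CurveRole | None = None) -> TransmissionCurve:
    df = pd.read_csv(path)
    if "transmission" not in df.columns or "gantry_angle_deg" not in df.columns:
        raise ValueError(f"{path}: expected columns gantry_angle_deg, transmission")
    if role is None:
        role = (CurveRole(df["role"].iloc[0]) if "role" in df.columns
                else CurveRole.CS_REFERENCE)
    return TransmissionCurve(grid=_grid_from_angles(df["gantry_angle_deg"].to_numpy(float)),
                             values=df["transmission"].to_numpy(float), role=role)


def read_attenuation_curve(path) -> AttenuationCurve:
    """Read an (angle, attenuation) table, e.g. a planning-system export."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "uncertainty_1sd"]
    if len(cols) < 2:
        raise ValueError(f"{path}: need angle and attenuation columns")
    angle_col = "gantry_angle_deg" if "gantry_angle_deg" in df.columns else cols[0]
    value_col = "attenuation" if "attenuation" in df.columns else cols[1]
    unc = (df["uncertainty_1sd"].to_numpy(float)
           if "uncertainty_1sd" in df.columns else None)
    return AttenuationCurve(grid=_grid_from_angles(df[angle_col].to_numpy(float)),
                            values=df[value_col].to_numpy(float), uncertainty=unc)


class GridConfig(BaseModel):
    """Grid section of a run configuration."""

    use_default: bool = True
    forbidden: list[float] = Field(default_factory=lambda: sorted(DEFAULT_FORBIDDEN))
    window_right: tuple[float, float] = DEFAULT_WINDOW_RIGHT
    window_left: tuple[float, float] = DEFAULT_WINDOW_LEFT


class RunConfig(BaseModel):
    """Validated run configuration (YAML-serialisable)."""

    grid: GridConfig = Field(default_factory=GridConfig)
    reference_temperature_c: float = 20.0
    reference_pressure_hpa: float = 1013.25
    compensation_subset: str = "windows"  # "windows" or "all"
    noise_sd: float = 0.0025
    artifact_amplitude: float = 0.004
    artifact_phase_deg: float = 120.0
    drift_total: float = 0.0
    replicate_count: int = 25
    seed: int = 1
    site: str = "OUH-like"

    @field_validator("compensation_subset")
    @classmethod
    def _subset(cls, v):
        if v not in ("windows", "all"):
            raise ValueError("compensation_subset must be 'windows' or 'all'")
        return v

    @field_validator("noise_sd", "artifact_amplitude")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("must be non-negative")
        return v

    def build_grid(self) -> GantryGrid:
        base = build_default_grid()
        angles = base.angles[~np.isin(base.angles, self.grid.forbidden)]
        return GantryGrid(angles=angles, forbidden=frozenset(self.grid.forbidden),
                          window_right=tuple(self.grid.window_right),
                          window_left=tuple(self.grid.window_left))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
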