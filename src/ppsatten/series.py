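"""Domain containers: reading series and angular curves.

All values are stored as dimensionless fractions (transmission near 1,
attenuation near 0); percent appears only in human-readable reports.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GantryGrid


class CurveRole(str, enum.Enum):
    """What a transmission curve represents in the analysis chain."""

    CS_MEASURED = "CS_measured"    # cryostat transmission from a measurement
    CS_REFERENCE = "CS_reference"  # stored reference cryostat curve
    CS_TPS = "CS_TPS"              # cryostat curve from the planning system
    CS_ADAPTED = "CS_adapted"      # reference adapted to the current setup
    CS_FIT = "CS_fit"              # reference plus fitted artifact term
    PPS = "PPS"                    # positioning-system transmission

    @property
    def is_cs(self) -> bool:
        return self is not CurveRole.PPS


CS_ONLY = "CS_only"
WITH_PPS = "with_PPS"
CONFIGURATIONS = (CS_ONLY, WITH_PPS)


@dataclass(frozen=True)
class AngularReadingSeries:
    """Per-gantry-angle electrometer readings with environment records.

    ``readings`` are raw (uncorrected) electrometer values; temperature
    and pressure are recorded per delivery so the air-density correction
    can be applied downstream.  ``acquisition_index`` preserves delivery
    order for drift diagnostics.
    """

    angles: np.ndarray
    readings: np.ndarray
    temperature_c: np.ndarray
    pressure_hpa: np.ndarray
    acquisition_index: np.ndarray
    site: str = ""
    session_id: str = ""
    configuration: str = CS_ONLY

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        readings = np.asarray(self.readings, dtype=float)
        n = angles.size
        temp = np.broadcast_to(np.asarray(self.temperature_c, dtype=float), (n,)).copy()
        pres = np.broadcast_to(np.asarray(self.pressure_hpa, dtype=float), (n,)).copy()
        idx = np.asarray(self.acquisition_index, dtype=int)
        if not (readings.size == temp.size == pres.size == idx.size == n):
            raise ValueError("all per-reading arrays must share one length")
        if n == 0:
            raise ValueError("empty reading series")
        if np.any(readings <= 0):
            raise ValueError("readings must be positive")
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(
                f"unknown configuration {self.configuration!r}; "
                f"expected one of {CONFIGURATIONS}"
            )
        for name, arr in (
            ("angles", angles), ("readings", readings),
            ("temperature_c", temp), ("pressure_hpa", pres),
            ("acquisition_index", idx),
        ):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return self.angles.size

    def index_of(self, angle: float, atol: float = 1e-9) -> int:
        hits = np.flatnonzero(np.isclose(self.angles, angle, atol=atol))
        if hits.size == 0:
            raise KeyError(f"no reading at gantry angle {angle}")
        return int(hits[0])


def _check_angular(angles: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    angles = np.asarray(angles, dtype=float)
    values = np.asarray(values, dtype=float)
    if angles.shape != values.shape or angles.ndim != 1 or angles.size == 0:
        raise ValueError("angles and values must be matching non-empty 1-D arrays")
    return angles, values


@dataclass(frozen=True)
class TransmissionCurve:
    """Dimensionless transmission per gantry angle, tagged by role.

    Cryostat-role curves are normalised to 1 at ``normalisation_angle``.
    """

    grid: GantryGrid
    values: np.ndarray
    role: CurveRole
    normalisation_angle: float = 90.0

    def __post_init__(self) -> None:
        angles, values = _check_angular(self.grid.angles, self.values)
        if np.any(values <= 0):
            raise ValueError("transmission values must be positive")
        object.__setattr__(self, "values", values)

    @property
    def angles(self) -> np.ndarray:
        return self.grid.angles

    def value_at(self, angle: float) -> float:
        hits = np.flatnonzero(np.isclose(self.angles, angle))
        if hits.size == 0:
            raise KeyError(f"curve has no value at {angle} deg")
        return float(self.values[hits[0]])

    def with_values(self, values: np.ndarray, role: CurveRole | None = None) -> "TransmissionCurve":
        return replace(self, values=np.asarray(values, dtype=float),
                       role=self.role if role is None else role)


@dataclass(frozen=True)
class UniformDoseSeries:
    """Corrected dose to the chamber after dividing out the cryostat ripple."""

    grid: GantryGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        _, values = _check_angular(self.grid.angles, self.values)
        if np.any(values <= 0):
            raise ValueError("uniform-dose values must be positive")
        object.__setattr__(self, "values", values)

    @property
    def angles(self) -> np.ndarray:
        return self.grid.angles


@dataclass(frozen=True)
class AttenuationCurve:
    """Fractional attenuation per gantry angle, optionally with 1-SD bars."""

    grid: GantryGrid
    values: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self) -> None:
        _, values = _check_angular(self.grid.angles, self.values)
        if np.any(values >= 1.0):
            raise ValueError("attenuation fractions must be below 1")
        object.__setattr__(self, "values", values)
        if self.uncertainty is not None:
            unc = np.asarray(self.uncertainty, dtype=float)
            if unc.shape != values.shape:
                raise ValueError("uncertainty must match values in shape")
            object.__setattr__(self, "uncertainty", unc)

    @property
    def angles(self) -> np.ndarray:
        return self.grid.angles

    def value_at(self, angle: float) -> float:
        hits = np.flatnonzero(np.isclose(self.angles, angle))
        if hits.size == 0:
            raise KeyError(f"curve has no value at {angle} deg")
        return float(self.values[hits[0]])
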