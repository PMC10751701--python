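"""Electrometer signal corrections and drift diagnostics.

Only the air-density (temperature/pressure) correction is applied: all
other chamber correction factors (recombination, polarity, beam quality)
cancel in the transmission ratios and are out of scope.  Machine-output
drift is quantified but deliberately not corrected, matching the
measurement protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ABSOLUTE_ZERO_C = -273.15


@dataclass(frozen=True)
class ReferenceConditions:
    """Reference temperature/pressure for the air-density correction.

    Defaults follow the standard dosimetry convention of 20 °C and
    1013.25 hPa; the analysis is invariant to this choice because every
    derived quantity is a ratio of readings taken under near-identical
    conditions.
    """

    temperature_c: float = 20.0
    pressure_hpa: float = 1013.25

    def __post_init__(self) -> None:
        if self.temperature_c <= ABSOLUTE_ZERO_C:
            raise ValueError("reference temperature below absolute zero")
        if self.pressure_hpa <= 0:
            raise ValueError("reference pressure must be positive")


DEFAULT_REFERENCE = ReferenceConditions()


def ktp_factor(temperature_c, pressure_hpa, ref: ReferenceConditions = DEFAULT_REFERENCE):
    """Air-density correction factor k_TP.

    k_TP = (273.15 + T)/(273.15 + T_ref) * P_ref/P; the corrected reading
    is raw * k_TP.  Vectorised over temperature and pressure.
    """
    t = np.asarray(temperature_c, dtype=float)
    p = np.asarray(pressure_hpa, dtype=float)
    if np.any(t <= ABSOLUTE_ZERO_C):
        raise ValueError("temperature below absolute zero")
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    return ((273.15 + t) / (273.15 + ref.temperature_c)) * (ref.pressure_hpa / p)


def temperature_pressure_correction(
    raw, temperature_c, pressure_hpa, ref: ReferenceConditions = DEFAULT_REFERENCE
):
    """Correct raw electrometer readings to reference air density."""
    return np.asarray(raw, dtype=float) * ktp_factor(temperature_c, pressure_hpa, ref)


def corrected_readings(series, ref: ReferenceConditions = DEFAULT_REFERENCE) -> np.ndarray:
    """Temperature/pressure-corrected readings of a series."""
    return temperature_pressure_correction(
        series.readings, series.temperature_c, series.pressure_hpa, ref
    )


def estimate_output_drift(series_first, series_last) -> float:
    """Relative machine-output change between repeats of one measurement.

    Returns mean(last)/mean(first) - 1: negative when the output dropped
    over the session.  The result is logged, never applied as a
    correction.
    """
    first = np.asarray(series_first, dtype=float)
    last = np.asarray(series_last, dtype=float)
    if first.size == 0 or last.size == 0:
        raise ValueError("drift estimation needs non-empty reading lists")
    return float(np.mean(last) / np.mean(first) - 1.0)
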