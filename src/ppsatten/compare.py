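"""Curve comparison and uncertainty summaries.

Implements the descriptive statistics used to compare attenuation curves
between sites, sessions, or against planning-system exports: per-angle
differences, SD-across-angles dispersion, replicate repeatability, and
the standard curve summary (peak, value at 180°, anterior-coil peak,
steepest per-degree change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import AttenuationCurve, TransmissionCurve

#: Angular region searched for the anterior-coil attenuation peak
#: (through the top of the circle): [310°, 360°) plus [0°, 50°].
COIL_REGION = ((310.0, 360.0), (0.0, 50.0))


@dataclass(frozen=True)
class CurveSummary:
    """Headline numbers of one attenuation curve (fractions, degrees)."""

    peak_attenuation: float
    peak_angle: float
    attenuation_at_180: float
    coil_peak: float
    coil_peak_angle: float
    max_per_degree_change: float

    def as_dict(self) -> dict:
        return {
            "peak_attenuation": self.peak_attenuation,
            "peak_angle_deg": self.peak_angle,
            "attenuation_at_180deg": self.attenuation_at_180,
            "coil_peak": self.coil_peak,
            "coil_peak_angle_deg": self.coil_peak_angle,
            "max_per_degree_change": self.max_per_degree_change,
        }


@dataclass(frozen=True)
class CurveComparison:
    """Per-angle difference (first - second) of two curves."""

    common_angles: np.ndarray
    differences: np.ndarray
    sd_across_angles: float
    max_abs_difference: float
    max_abs_angle: float
    summary_first: CurveSummary
    summary_second: CurveSummary

    def difference_at(self, angle: float) -> float:
        hits = np.flatnonzero(np.isclose(self.common_angles, angle))
        if hits.size == 0:
            raise KeyError(f"no common angle {angle}")
        return float(self.differences[hits[0]])

    def within_band(self, band: float) -> float:
        """Fraction of common angles with |difference| <= band."""
        return float(np.mean(np.abs(self.differences) <= band))


def _sorted_by_angle(curve) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(curve.angles)
    return curve.angles[order], curve.values[order]


def summarize(curve: AttenuationCurve) -> CurveSummary:
    """Standard summary of an attenuation curve.

    Argmax ties are broken toward the smaller gantry angle.  The
    steepest per-degree change is evaluated only where consecutive grid
    angles are 1° apart, so the sparse 5° region cannot masquerade as a
    gradient.  The value at 180° requires that angle on the grid.
    """
    angles, values = _sorted_by_angle(curve)
    i_peak = int(np.argmax(values))  # first occurrence = smallest angle
    at180_hits = np.flatnonzero(np.isclose(angles, 180.0))
    if at180_hits.size == 0:
        raise ValueError("curve has no value at 180 deg")
    coil_mask = np.zeros_like(angles, dtype=bool)
    for lo, hi in COIL_REGION:
        coil_mask |= (angles >= lo) & (angles < hi) if hi == 360.0 else \
                     (angles >= lo) & (angles <= hi)
    if not coil_mask.any():
        raise ValueError("no grid angles in the anterior-coil region")
    coil_angles, coil_values = angles[coil_mask], values[coil_mask]
    i_coil = int(np.argmax(coil_values))
    spacing = np.diff(angles)
    one_deg = np.isclose(spacing, 1.0)
    per_degree = np.abs(np.diff(values))[one_deg]
    max_change = float(per_degree.max()) if per_degree.size else float("nan")
    return CurveSummary(
        peak_attenuation=float(values[i_peak]),
        peak_angle=float(angles[i_peak]),
        attenuation_at_180=float(values[at180_hits[0]]),
        coil_peak=float(coil_values[i_coil]),
        coil_peak_angle=float(coil_angles[i_coil]),
        max_per_degree_change=max_change,
    )


def difference_curve(first: AttenuationCurve, second: AttenuationCurve) -> CurveComparison:
    """Compare two attenuation curves on their common angles."""
    common = np.intersect1d(first.angles, second.angles)
    if common.size == 0:
        raise ValueError("curves share no gantry angles")
    f = {a: v for a, v in zip(first.angles, first.values)}
    s = {a: v for a, v in zip(second.angles, second.values)}
    diffs = np.array([f[a] - s[a] for a in common])
    i_max = int(np.argmax(np.abs(diffs)))
    return CurveComparison(
        common_angles=common,
        differences=diffs,
        sd_across_angles=float(np.std(diffs, ddof=1)) if common.size > 1 else 0.0,
        max_abs_difference=float(abs(diffs[i_max])),
        max_abs_angle=float(common[i_max]),
        summary_first=summarize(first),
        summary_second=summarize(second),
    )


def _aligned_values(curve, reference) -> np.ndarray:
    if not np.array_equal(np.sort(curve.angles), np.sort(reference.angles)):
        raise ValueError("curve does not share the reference grid")
    ref_order = {a: i for i, a in enumerate(reference.angles)}
    idx = np.array([ref_order[a] for a in curve.angles])
    out = np.empty_like(curve.values)
    out[idx] = curve.values
    return out


def sd_of_difference_from_reference(
    curves: list[TransmissionCurve],
    reference: TransmissionCurve,
) -> tuple[np.ndarray, float]:
    """Dispersion of each curve around a reference, and the mean.

    For each curve: the SD over gantry angles of (curve - reference).
    A constant offset common to curve and reference cancels; the
    sinusoidal-artifact compensation drives this statistic down to the
    noise floor.  Returns (per-curve SDs, their mean).
    """
    if not curves:
        raise ValueError("need at least one curve")
    sds = np.array([
        float(np.std(_aligned_values(c, reference) - reference.values, ddof=1))
        for c in curves
    ])
    return sds, float(np.mean(sds))


def session_repeatability(replicates: list[AttenuationCurve]) -> np.ndarray:
    """Per-angle sample SD across replicate attenuation curves."""
    if len(replicates) < 2:
        raise ValueError("repeatability needs at least two replicates")
    base = replicates[0]
    stack = np.vstack([_aligned_values(r, base) for r in replicates])
    return np.std(stack, axis=0, ddof=1)
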