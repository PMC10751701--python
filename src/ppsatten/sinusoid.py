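"""Cosine artifact model and its least-squares compensation.

Sub-millimetre detector/phantom misalignment and residual air cavities
produce a gantry-periodic, cosine-shaped error in the measured
transmission.  Because every curve is normalised to 1 at 90°, the error
model is anchored to vanish there:

    delta(phi) = a * [cos(phi - b) - cos(90° - b)],

with amplitude a >= 0 and phase b in [0°, 360°).  Expanding,

    delta(phi) = A*cos(phi) + B*(sin(phi) - 1),   A = a cos b, B = a sin b,

so the apparently nonlinear (a, b) fit is an exact linear least-squares
problem in (A, B): no initialisation, no convergence tolerance, a unique
global optimum (up to the (a, b) <-> (-a, b+180°) degeneracy, resolved by
the convention a >= 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import CurveRole, TransmissionCurve

#: Amplitudes below this are reported as the degenerate fit (a, b) = (0, 0).
DEGENERATE_AMPLITUDE = 1e-12


@dataclass(frozen=True)
class SinusoidFit:
    """Fitted cosine-artifact parameters.

    Attributes
    ----------
    amplitude:
        a >= 0, dimensionless (transmission units).
    phase_deg:
        b in [0, 360) degrees.
    residual_rms:
        RMS of (measured - reference - model) over the fit angles.
    fit_angles:
        The gantry angles the fit used.
    """

    amplitude: float
    phase_deg: float
    residual_rms: float
    fit_angles: np.ndarray

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "phase_deg", float(self.phase_deg) % 360.0)
        object.__setattr__(self, "fit_angles",
                           np.asarray(self.fit_angles, dtype=float))


def _term(amplitude: float, phase_deg: float, angles) -> np.ndarray:
    phi = np.deg2rad(np.asarray(angles, dtype=float))
    b = np.deg2rad(phase_deg)
    return amplitude * (np.cos(phi - b) - np.cos(np.deg2rad(90.0) - b))


def compensation_term(fit: SinusoidFit, angles) -> np.ndarray | float:
    """Evaluate the artifact model a[cos(phi-b) - cos(90°-b)].

    Identically zero at phi = 90° for every (a, b).
    """
    out = _term(fit.amplitude, fit.phase_deg, angles)
    return float(out) if np.isscalar(angles) else out


def _aligned_difference(
    measured: TransmissionCurve,
    reference: TransmissionCurve,
    angle_subset,
) -> tuple[np.ndarray, np.ndarray]:
    if angle_subset is None:
        common = np.intersect1d(measured.angles, reference.angles)
    else:
        common = np.asarray(sorted(angle_subset), dtype=float)
    m = {a: v for a, v in zip(measured.angles, measured.values)}
    r = {a: v for a, v in zip(reference.angles, reference.values)}
    missing = [a for a in common if a not in m or a not in r]
    if missing:
        raise ValueError(f"angles absent from one curve: {missing[:5]}")
    diff = np.array([m[a] - r[a] for a in common])
    return common, diff


def fit_artifact(
    measured: TransmissionCurve,
    reference: TransmissionCurve,
    angle_subset=None,
) -> SinusoidFit:
    """Least-squares fit of the cosine artifact between two curves.

    Minimises sum over the angle subset of
    [measured - reference - a(cos(phi-b) - cos(90°-b))]^2.  With
    ``angle_subset=None`` all common angles are used (full-circle,
    cryostat-to-reference case); passing the open-window angles gives the
    restricted fit used when the positioning system blocks the rest of
    the circle.  Angles are equally weighted regardless of local grid
    spacing.
    """
    angles, diff = _aligned_difference(measured, reference, angle_subset)
    if angles.size < 3:
        raise ValueError("need at least 3 angles to fit the artifact model")
    phi = np.deg2rad(angles)
    design = np.column_stack([np.cos(phi), np.sin(phi) - 1.0])
    (A, B), *_ = np.linalg.lstsq(design, diff, rcond=None)
    amplitude = float(np.hypot(A, B))
    if amplitude < DEGENERATE_AMPLITUDE:
        amplitude, phase = 0.0, 0.0
    else:
        phase = float(np.degrees(np.arctan2(B, A)) % 360.0)
    resid = diff - _term(amplitude, phase, angles)
    return SinusoidFit(amplitude=amplitude, phase_deg=phase,
                       residual_rms=float(np.sqrt(np.mean(resid**2))),
                       fit_angles=angles)


def apply_artifact(
    reference: TransmissionCurve,
    fit: SinusoidFit,
    role: CurveRole = CurveRole.CS_FIT,
) -> TransmissionCurve:
    """Shift a reference curve by the fitted artifact term.

    The output role distinguishes the full-circle compensation product
    (``CS_fit``) from the setup-adapted curve used in the attenuation
    chain (``CS_adapted``).  The value at 90° is always preserved.
    """
    values = reference.values + _term(fit.amplitude, fit.phase_deg, reference.angles)
    return reference.with_values(values, role=role)
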