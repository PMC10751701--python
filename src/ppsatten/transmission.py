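"""Core transmission/attenuation decomposition.

The chamber signal at gantry angle phi factorises as

    D(phi) = D(90) * T_CS(phi) * T_PPS(phi),

where T_CS is the cryostat transmission ripple (normalised to 1 at 90°)
and T_PPS the positioning-system transmission.  The stages below peel the
factors apart: normalise at 90°, divide out the cryostat curve, normalise
by the mean over the open windows (where T_PPS = 1 by geometry), and
convert transmission to attenuation A = 1 - T.
"""

from __future__ import annotations

import numpy as np

from .corrections import DEFAULT_REFERENCE, ReferenceConditions, corrected_readings
from .grid import GantryGrid
from .series import (
    AngularReadingSeries,
    AttenuationCurve,
    CurveRole,
    TransmissionCurve,
    UniformDoseSeries,
)


def normalize_at(
    series: AngularReadingSeries,
    grid: GantryGrid | None = None,
    angle: float = 90.0,
    role: CurveRole = CurveRole.CS_MEASURED,
    ref: ReferenceConditions = DEFAULT_REFERENCE,
) -> TransmissionCurve:
    """Corrected readings divided by the corrected reading at ``angle``.

    The normalisation angle must be present in the series; interpolating
    a normalisation value would silently mix noise into every angle, so a
    missing entry is an error.
    """
    corrected = corrected_readings(series, ref)
    i0 = series.index_of(angle)  # KeyError if absent
    values = corrected / corrected[i0]
    if grid is None:
        grid = GantryGrid(angles=series.angles, forbidden=frozenset())
    elif not np.array_equal(grid.angles, series.angles):
        raise ValueError("series angles do not match the supplied grid")
    return TransmissionCurve(grid=grid, values=values, role=role,
                             normalisation_angle=angle)


def normalize_cs(
    series: AngularReadingSeries,
    grid: GantryGrid | None = None,
    ref: ReferenceConditions = DEFAULT_REFERENCE,
) -> TransmissionCurve:
    """Cryostat transmission from a PPS-free session (ratio to 90°)."""
    return normalize_at(series, grid=grid, angle=90.0, role=CurveRole.CS_MEASURED, ref=ref)


def uniform_dose(
    series: AngularReadingSeries,
    cs: TransmissionCurve,
    ref: ReferenceConditions = DEFAULT_REFERENCE,
) -> UniformDoseSeries:
    """Dose the chamber would see with a ripple-free cryostat.

    Divides the corrected reading at each angle by the cryostat
    transmission there.  The CS curve must cover exactly the series grid
    (no interpolation) and must be a cryostat-role curve.
    """
    if not cs.role.is_cs:
        raise ValueError(f"need a cryostat-role curve, got {cs.role.value}")
    if not np.array_equal(np.sort(cs.angles), np.sort(series.angles)):
        raise ValueError("cryostat curve angles do not match the series")
    corrected = corrected_readings(series, ref)
    # align cs values to series angle order
    order = {a: v for a, v in zip(cs.angles, cs.values)}
    cs_vals = np.array([order[a] for a in series.angles])
    return UniformDoseSeries(grid=cs.grid if np.array_equal(cs.angles, series.angles)
                             else GantryGrid(angles=series.angles, forbidden=frozenset()),
                             values=corrected / cs_vals)


def pps_transmission(uniform: UniformDoseSeries, grid: GantryGrid) -> TransmissionCurve:
    """Positioning-system transmission via open-window normalisation.

    T_PPS(phi) = D_uniform(phi) / <D_uniform> over the pooled open
    windows, where the beam misses the PPS and the true transmission is
    1.  Pooling both windows averages the per-angle noise out of the
    normalisation constant.
    """
    mask = grid.window_mask(uniform.angles)
    lo_r, hi_r = grid.window_right
    lo_l, hi_l = grid.window_left
    in_r = (uniform.angles >= lo_r) & (uniform.angles <= hi_r)
    in_l = (uniform.angles >= lo_l) & (uniform.angles <= hi_l)
    if in_r.sum() < 2 or in_l.sum() < 2:
        raise ValueError("each open window must contain at least two angles")
    window_mean = float(np.mean(uniform.values[mask]))
    return TransmissionCurve(grid=grid if np.array_equal(grid.angles, uniform.angles)
                             else uniform.grid,
                             values=uniform.values / window_mean, role=CurveRole.PPS)


def attenuation(t: TransmissionCurve) -> AttenuationCurve:
    """Attenuation A(phi) = 1 - T_PPS(phi)."""
    if t.role is not CurveRole.PPS:
        raise ValueError(f"attenuation is defined for PPS curves, got {t.role.value}")
    return AttenuationCurve(grid=t.grid, values=1.0 - t.values)
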