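"""Gantry-angle grid for angular transmission measurements.

The measurement protocol samples the full gantry circle non-uniformly:
1° steps through the lower half (90°–270°, where the couch and coils sit
in the beam path) and 5° steps through the upper half.  A small set of
angles is forbidden because the beam would irradiate the superconducting
pipe joining the two magnet segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gantry-angle windows (closed intervals, degrees) where the beam misses
#: the patient positioning system entirely: beam from the right / left as
#: seen from the foot end of the bore.
DEFAULT_WINDOW_RIGHT: tuple[float, float] = (50.0, 105.0)
DEFAULT_WINDOW_LEFT: tuple[float, float] = (255.0, 310.0)

#: Angles excluded on the default grid (superconducting-pipe shadow for a
#: 5x5 cm^2 field).
DEFAULT_FORBIDDEN: frozenset[float] = frozenset({10.0, 15.0})


@dataclass(frozen=True)
class GantryGrid:
    """Ordered set of gantry angles with open-window metadata.

    Parameters
    ----------
    angles:
        Angles in degrees, in acquisition order, each in [0, 360).
    forbidden:
        Angles that must not appear in ``angles``.
    window_right, window_left:
        Closed angular intervals where the positioning system is outside
        the beam path; used to normalise the PPS transmission.
    """

    angles: np.ndarray
    forbidden: frozenset = DEFAULT_FORBIDDEN
    window_right: tuple[float, float] = DEFAULT_WINDOW_RIGHT
    window_left: tuple[float, float] = DEFAULT_WINDOW_LEFT

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("grid needs a non-empty 1-D angle list")
        if np.any((angles < 0.0) | (angles >= 360.0)):
            raise ValueError("gantry angles must lie in [0, 360)")
        if np.unique(angles).size != angles.size:
            raise ValueError("duplicate gantry angles in grid")
        if np.isin(angles, sorted(self.forbidden)).any():
            raise ValueError("grid contains forbidden gantry angles")
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))

    def __len__(self) -> int:
        return self.angles.size

    def __contains__(self, angle: float) -> bool:
        return bool(np.any(np.isclose(self.angles, angle)))

    def window_mask(self, angles: np.ndarray | None = None) -> np.ndarray:
        """Boolean mask of angles inside the pooled open windows."""
        a = self.angles if angles is None else np.asarray(angles, dtype=float)
        lo_r, hi_r = self.window_right
        lo_l, hi_l = self.window_left
        return ((a >= lo_r) & (a <= hi_r)) | ((a >= lo_l) & (a <= hi_l))

    def window_angles(self) -> np.ndarray:
        return self.angles[self.window_mask()]


def build_default_grid() -> GantryGrid:
    """Default 214-angle acquisition grid.

    1° steps from 90° to 270°, then 5° steps from 275° around through 0°
    to 85°, with the forbidden angles 10° and 15° removed.  The ordering
    follows the acquisition sequence (start at 90°, gantry rotating
    through 180°), which matters when modelling machine-output drift.
    """
    dense = np.arange(90.0, 271.0, 1.0)
    sparse_upper = np.arange(275.0, 360.0, 5.0)
    sparse_top = np.arange(0.0, 90.0, 5.0)
    angles = np.concatenate([dense, sparse_upper, sparse_top])
    angles = angles[~np.isin(angles, sorted(DEFAULT_FORBIDDEN))]
    return GantryGrid(angles=angles)
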