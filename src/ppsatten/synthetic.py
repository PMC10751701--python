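"""Synthetic measurement generator.

Emulates the angular attenuation measurement on a high-field MR-linac:
a parametric positioning-system (PPS) attenuation profile and cryostat
(CS) transmission ripple define the truth; a session is the forward model

    D(phi) = D90 * T_CS(phi) * T_PPS(phi)
             * (1 + artifact(phi)) * (1 + drift * order_fraction)
             * (1 + noise),

sampled on the acquisition grid, with the cosine measurement artifact,
linear machine-output drift in delivery order, and Gaussian per-reading
noise proportional to signal.  Raw electrometer readings are back-computed
from the recorded temperature/pressure so that the downstream air-density
correction recovers the signal exactly.

The generator's defaults are the study conditions: per-reading noise SD
0.25% of signal, artifact amplitude 0.004, and a 0.35% output drop over a
session for the drift scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .corrections import DEFAULT_REFERENCE, ktp_factor
from .grid import DEFAULT_WINDOW_LEFT, DEFAULT_WINDOW_RIGHT, GantryGrid
from .series import CS_ONLY, WITH_PPS, AngularReadingSeries, CurveRole, TransmissionCurve
from .sinusoid import _term

OUH_LIKE = "OUH-like"
UAS_LIKE = "UAS-like"
SITE_LABELS = (OUH_LIKE, UAS_LIKE)


# --------------------------------------------------------------------------
# Ground truths
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CSGroundTruth:
    """True cryostat transmission ripple: low-order Fourier series.

    T_CS(phi) = 1 + sum_k [c_k cos(k phi) + s_k sin(k phi)] - offset,
    with the offset chosen so that T_CS(90°) = 1 exactly.  The default
    coefficients reproduce a realistic weld-pattern ripple spanning
    roughly 0.993-1.010.
    """

    harmonics: tuple = (
        # (order, cosine weight, sine weight)
        (1, -0.004596, -0.004596),
        (2, -0.001750, -0.003031),
        (3, -0.001200, 0.0),
    )

    def _ripple(self, angles) -> np.ndarray:
        phi = np.deg2rad(np.asarray(angles, dtype=float))
        out = np.zeros_like(phi)
        for order, cw, sw in self.harmonics:
            out += cw * np.cos(order * phi) + sw * np.sin(order * phi)
        return out

    def evaluate(self, angles) -> np.ndarray:
        """Transmission at the given gantry angles (T(90°) = 1 exactly)."""
        offset = self._ripple(90.0)
        return 1.0 + self._ripple(angles) - offset

    def curve(self, grid: GantryGrid, role: CurveRole = CurveRole.CS_TPS) -> TransmissionCurve:
        """Noiseless truth evaluated on a grid, e.g. as the stored reference."""
        return TransmissionCurve(grid=grid, values=self.evaluate(grid.angles), role=role)


@dataclass(frozen=True)
class PPSGroundTruth:
    """True PPS attenuation profile: anchored, shape-preserving cubic.

    The profile is exactly zero inside the open windows, interpolates the
    anchors with a monotone (PCHIP) piecewise cubic — which cannot
    overshoot the local anchor range, keeping values in [0, 0.30] — and
    wraps periodically across 0°/360° through the anterior-coil bump.
    """

    site_label: str
    anchors: tuple  # ((angle_deg, attenuation_fraction), ...)
    window_right: tuple[float, float] = DEFAULT_WINDOW_RIGHT
    window_left: tuple[float, float] = DEFAULT_WINDOW_LEFT

    def _interpolator(self) -> PchipInterpolator:
        pts = sorted((float(a) % 360.0, float(v)) for a, v in self.anchors)
        ang = np.array([p[0] for p in pts])
        val = np.array([p[1] for p in pts])
        if np.unique(ang).size != ang.size:
            raise ValueError("duplicate anchor angles")
        # periodic extension so the coil bump wraps smoothly across 0/360
        ang_ext = np.concatenate([ang - 360.0, ang, ang + 360.0])
        val_ext = np.tile(val, 3)
        return PchipInterpolator(ang_ext, val_ext)

    def _window_mask(self, angles: np.ndarray) -> np.ndarray:
        a = angles % 360.0
        lo_r, hi_r = self.window_right
        lo_l, hi_l = self.window_left
        return ((a >= lo_r) & (a <= hi_r)) | ((a >= lo_l) & (a <= hi_l))

    def evaluate(self, angles) -> np.ndarray:
        """Attenuation fraction at the given gantry angles."""
        a = np.atleast_1d(np.asarray(angles, dtype=float)) % 360.0
        out = self._interpolator()(a)
        out[self._window_mask(a)] = 0.0
        return out if np.ndim(angles) else out[0] * np.ones(())

    def transmission(self, angles) -> np.ndarray:
        return 1.0 - self.evaluate(angles)

    def attenuation_curve(self, grid: GantryGrid):
        from .series import AttenuationCurve

        return AttenuationCurve(grid=grid, values=np.atleast_1d(self.evaluate(grid.angles)))


# Anchor tables.  Printed constraints: peak 0.246 at 122° (both sites;
# 0.245 at 238° for the UAS-like profile), 0.113 at 180°, coil peaks
# 0.0088/0.0069, site difference -0.011 at 115° and +0.011 at 245°, ramps
# rising 0 -> ~0.25 over ~15° with per-degree changes near 0.016.
_MID_SECTION = (
    (127.0, 0.175), (135.0, 0.128), (150.0, 0.118), (165.0, 0.1145),
    (180.0, 0.113),
    (195.0, 0.1145), (210.0, 0.118), (225.0, 0.128), (233.0, 0.175),
)

_WINDOW_EDGES = ((50.0, 0.0), (105.0, 0.0), (255.0, 0.0), (310.0, 0.0))

# anterior-coil bump, unit height at 0°, zero by the window edges
_COIL_UNIT = (
    (315.0, 0.0), (322.0, 0.05), (332.0, 0.20), (342.0, 0.50),
    (350.0, 0.82), (355.0, 0.95), (0.0, 1.0), (5.0, 0.95), (13.0, 0.82),
    (21.0, 0.50), (31.0, 0.20), (41.0, 0.05), (48.0, 0.0),
)

_RAMPS = {
    OUH_LIKE: (
        (107.0, 0.0), (111.0, 0.060), (115.0, 0.1257), (119.0, 0.196),
        (122.0, 0.246),
        (238.0, 0.246), (241.0, 0.196), (245.0, 0.1367), (249.0, 0.068),
        (253.0, 0.0),
    ),
    UAS_LIKE: (
        (107.0, 0.0), (111.0, 0.068), (115.0, 0.1367), (119.0, 0.203),
        (122.0, 0.246),
        (238.0, 0.245), (241.0, 0.190), (245.0, 0.1257), (249.0, 0.060),
        (253.0, 0.0),
    ),
}

_COIL_PEAK = {OUH_LIKE: 0.0088, UAS_LIKE: 0.0069}


def make_default_anchors(site_label: str) -> PPSGroundTruth:
    """Default ground-truth profile for one of the two emulated sites."""
    if site_label not in SITE_LABELS:
        raise ValueError(
            f"unknown site label {site_label!r}; expected one of {SITE_LABELS}"
        )
    coil = tuple((a, v * _COIL_PEAK[site_label]) for a, v in _COIL_UNIT)
    anchors = _WINDOW_EDGES + _RAMPS[site_label] + _MID_SECTION + coil
    return PPSGroundTruth(site_label=site_label, anchors=anchors)


def default_cs_truth() -> CSGroundTruth:
    return CSGroundTruth()


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated measurement session.

    noise_sd is the per-reading Gaussian SD as a fraction of signal
    (default 0.0025, the measured repeatability); artifact amplitude and
    phase parametrise the cosine measurement artifact; drift_total is the
    relative output change from first to last delivery (default -0.0035,
    the observed session drop; the replicate protocols set it explicitly).
    nominal_reading is the collected charge at 90° in nC for a 100 MU
    delivery with a Farmer-type chamber.
    """

    noise_sd: float = 0.0025
    artifact_amplitude: float = 0.004
    artifact_phase_deg: float = 120.0
    drift_total: float = -0.0035
    replicate_count: int = 1
    seed: int = 0
    nominal_reading: float = 20.0
    temperature_c: float | tuple = 21.0
    pressure_hpa: float | tuple = 1008.0
    #: gantry-angle positioning jitter (deg, 1 SD); sensitivity scenario,
    #: off by default
    angle_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.angle_jitter_sd < 0:
            raise ValueError("angle_jitter_sd must be non-negative")
        if self.artifact_amplitude < 0:
            raise ValueError("artifact_amplitude must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be at least 1")
        if self.nominal_reading <= 0:
            raise ValueError("nominal_reading must be positive")


def simulate_session(
    config: SimulationConfig,
    grid: GantryGrid,
    cs_truth: CSGroundTruth,
    pps_truth: PPSGroundTruth | None = None,
    site: str | None = None,
    session_id: str = "sim",
) -> AngularReadingSeries:
    """Simulate one acquisition session over the grid.

    With ``pps_truth=None`` the session is a cryostat-only run
    (T_PPS = 1).  The random stream is derived from (seed, configuration)
    so a CS-only and a with-PPS session at the same seed draw independent
    noise; repeated calls with identical arguments are bit-identical.
    """
    angles = grid.angles
    n = angles.size
    role = 0 if pps_truth is None else 1
    rng = np.random.default_rng([int(config.seed), role])
    # positioning jitter shifts the angle the beam truly hits; the row is
    # still recorded at the nominal angle
    true_angles = angles
    if config.angle_jitter_sd > 0:
        true_angles = angles + rng.normal(0.0, config.angle_jitter_sd, size=n)
    tcs = cs_truth.evaluate(true_angles)
    tpps = (pps_truth.transmission(true_angles) if pps_truth is not None
            else np.ones(n))
    artifact = _term(config.artifact_amplitude, config.artifact_phase_deg, angles)
    frac = np.arange(n) / max(n - 1, 1)
    signal = (config.nominal_reading * tcs * tpps
              * (1.0 + artifact) * (1.0 + config.drift_total * frac))
    if config.noise_sd > 0:
        signal = signal * (1.0 + rng.normal(0.0, config.noise_sd, size=n))
    temp = np.broadcast_to(np.asarray(config.temperature_c, dtype=float), (n,))
    pres = np.broadcast_to(np.asarray(config.pressure_hpa, dtype=float), (n,))
    raw = signal / ktp_factor(temp, pres, DEFAULT_REFERENCE)
    if site is None:
        site = pps_truth.site_label if pps_truth is not None else "CS"
    return AngularReadingSeries(
        angles=angles, readings=raw, temperature_c=temp, pressure_hpa=pres,
        acquisition_index=np.arange(n), site=site, session_id=session_id,
        configuration=CS_ONLY if pps_truth is None else WITH_PPS,
    )
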