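# Methods

## Signal model

A delivery at gantry angle φ deposits a chamber signal that factorises as

    D(φ) = D(90°) · T_CS(φ) · T_PPS(φ),

where `T_CS` is the cryostat transmission ripple (dimensionless, ≈ 1,
defined as 1 at φ = 90°) and `T_PPS` the transmission of the patient
positioning system.  Electrometer readings are corrected to reference
air density with

    k_TP = (273.15 + T)/(273.15 + T_ref) · P_ref/P,

T in °C, P in hPa; reference conditions default to 20 °C / 1013.25 hPa
(standard dosimetry convention — the published protocol does not state
its reference values, and every derived quantity is a ratio in which the
choice cancels).  Recombination, polarity and beam-quality factors
cancel in those ratios as well and are not modelled.  Machine-output
drift is *monitored* (mean of last repeats over mean of first repeats,
minus one) but never applied as a correction, matching the measurement
protocol.

The attenuation extraction proceeds in four steps on the acquisition
grid (no interpolation across missing or forbidden angles):

1. normalise the with-PPS session at 90° (the 90° entry must exist;
   interpolating a normalisation value would smear its noise over every
   angle, so a missing entry is an error);
2. adapt the stored cryostat reference to the current setup by fitting
   the cosine artifact (below) over the open windows and adding the
   fitted term to the reference ("adapted" cryostat curve);
3. divide the corrected readings by the adapted cryostat curve
   ("uniform-cryostat" dose) and normalise by the pooled mean over both
   open windows [50°, 105°] and [255°, 310°], where the beam misses the
   PPS and the true transmission is 1 — pooling both windows averages
   per-angle noise out of the normalisation constant;
4. attenuation `A_PPS(φ) = 1 − T_PPS(φ)`.

Window endpoints are treated as closed intervals on grid angles and are
configurable.  Whether lateral-beam analyses should use each window
separately is not settled by the protocol; the pooled mean is
implemented, and it forces the mean attenuation over the windows to be
exactly zero (a property the tests assert).  Attenuation is stored as a
fraction everywhere; percent appears only in human-readable reports.

## Cosine artifact compensation

Sub-millimetre chamber/phantom misalignment and residual air cavities
produce a gantry-periodic error in a measured transmission curve.
Because all curves are normalised at 90°, the error model is anchored to
vanish there:

    δ(φ) = a·[cos(φ − b) − cos(90° − b)],  a ≥ 0,  b ∈ [0°, 360°).

Expanding gives `δ(φ) = A·cos φ + B·(sin φ − 1)` with `A = a·cos b`,
`B = a·sin b`, so the fit of (a, b) to `measured − reference` is an
exact linear least-squares problem: no initialisation, no iteration, a
unique optimum.  The sign degeneracy (a, b) ↔ (−a, b + 180°) is resolved
by the convention a ≥ 0; amplitudes below 1e−12 are reported as the
degenerate fit (0, 0).  Angles on the non-uniform grid are equally
weighted (the protocol does not define a weighting; the dense 1° region
therefore dominates the full-circle fit).  Two fitting contexts exist:
full circle (cryostat measurement against a reference) and restricted to
the open windows (with the PPS in the bore, where only the windows see a
pure cryostat signal).  Least-squares optimality guarantees the post-fit
residual RMS never exceeds the pre-fit RMS.

The artifact is *injected* multiplicatively on the signal by the
generator but *modelled* additively on the normalised transmission, as
the published model does.  To first order the two coincide; the
difference is O(a·|T−1|) ≤ 1e−4 at the amplitudes in play (a ≤ 0.01),
which the noise-free round-trip tests bound directly.

## Synthetic-data generator

The generator is the package's test bed: it produces measurement tables
format-identical to real sessions.

**PPS ground truth.**  A shape-preserving (PCHIP) piecewise cubic
through anchor points, exactly zero inside both open windows, extended
periodically across 0°/360° so the anterior-coil bump wraps smoothly.
PCHIP cannot overshoot the local anchor range, keeping the profile
inside [0, 0.30].  Anchors encode the published values: peak 0.246 at
122° (0.246/0.245 at 238° for the OUH-like/UAS-like profiles), 0.113 at
180°, coil peaks 0.0088/0.0069 at 0°, and ramp anchors at 115°/245°
placed so the site difference is −0.011 at 115° and +0.011 at 245° (the
sign convention OUH−UAS = −0.011 at 115° is a package convention; the
published difference plot does not state its orientation).  The ramps
rise from 0 to the peak over ≈ 15°; with the printed rise the mean slope
is 1.64 %/°, and the realised per-degree change on the 1° grid peaks at
≈ 2.2 %/° (a perfectly uniform 1.6 %/° ramp and the printed 15° rise are
not simultaneously attainable).

**Cryostat ground truth.**  A three-harmonic Fourier series with frozen
default coefficients, offset so T_CS(90°) = 1 exactly; the default range
is ≈ [0.993, 1.010], the span of a compensated cryostat
characterisation.

**Forward model.**  One reading per grid angle in acquisition order
(start at 90°, through 270°, then 275°…355°, 0°…85°):

    reading = D90 · T_CS · T_PPS · (1 + δ(φ)) · (1 + drift·f) · (1 + ε),

with `f` the acquisition-order fraction (drift is linear in order; only
the session start/end difference is reported in practice, so a linear
profile is the minimal model), ε Gaussian with SD `noise_sd` (default
0.0025, the measured repeatability), and δ the cosine artifact (default
a = 0.004, b = 120°).  Raw table values are back-computed through k_TP
from the recorded temperature/pressure (defaults 21 °C, 1008 hPa), so
the correction stage is exercised on every synthetic table.  Defaults:
`drift_total = −0.0035` (midpoint of the observed 0.33–0.40 % session
drop) for the drift scenario; the replicate protocols set drift to zero
because the published dispersion statistics are quoted under noise +
artifact conditions only.  An optional angle-jitter scenario
(`angle_jitter_sd`, default 0) evaluates the truth at φ + N(0, σ) while
recording the nominal angle, which inflates repeatability near the steep
ramps in proportion to |dA/dφ|.

Randomness: each session draws from a stream keyed by (seed, session
role), so CS-only and with-PPS sessions at the same seed are independent
and every call is bit-reproducible.  Replicate k of a study uses seed
`base_seed + k`; the three-series compensation study uses seeds
`base_seed + 10 + i`.

**What the generator does not emulate.**  No beam transport or
chamber-response modelling in the magnetic field, no couch/coil CAD
geometry, no recombination/polarity effects, no inter-session setup
variation beyond the cosine artifact, and noise is homoscedastic in
relative terms.  Passing tests therefore demonstrate correctness of the
*analysis* under the stated statistical model, not detector physics.

## Replicate protocols and statistics

`run_replicate_study` simulates, per replicate, one CS-only and one
with-PPS session, runs the full chain against the stored noiseless
cryostat reference curve (standing in for the planning-system cryostat
table), and averages the per-replicate attenuation curves; the CS-only
sessions feed the dispersion diagnostics.  With 25 replicates at noise
SD 0.0025 the per-angle Monte-Carlo SE of the mean is ≈ 5e−4.

"Dispersion from reference" is the SD over grid angles of
(curve − reference), averaged over curves — the operationalisation under
which artifact compensation reduces the statistic to the noise floor.  A
constant offset common to curve and reference cancels.  Curve summaries
break argmax ties toward the smaller angle; the anterior-coil peak is
searched in [310°, 360°) ∪ [0°, 50°]; the steepest per-degree change is
evaluated only where consecutive grid angles are 1° apart.

## Numerical notes and limitations

* All angle handling is in degrees; trigonometry converts internally.
* Exact float equality of grid angles is required when aligning curves
  (the package never interpolates silently); duplicate table rows for
  the same (session, angle) are averaged with a logged warning.
* The phase b of the artifact fit is poorly determined when the
  amplitude approaches the noise scale — the noisy 90° normalisation
  reading leaks a near-constant term into the windowed fit — while the
  fitted compensation *term* remains accurate; diagnostics should be
  read accordingly.
* Planning-system attenuation curves are accepted only as plain
  (angle, attenuation) tables; no proprietary formats, no dose
  calculation, and no hypothesis testing between sites (the comparison
  statistics are descriptive, as in the underlying QA practice).
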