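import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppsatten import (
    CurveRole,
    SinusoidFit,
    TransmissionCurve,
    apply_artifact,
    compensation_term,
    fit_artifact,
)
from ppsatten.sinusoid import _term

amplitudes = st.floats(min_value=1e-4, max_value=0.02)
phases = st.floats(min_value=0.0, max_value=359.9)


def _fit(a, b):
    return SinusoidFit(amplitude=a, phase_deg=b, residual_rms=0.0,
                       fit_angles=np.array([]))


def _curve(grid, values, role=CurveRole.CS_MEASURED):
    return TransmissionCurve(grid=grid, values=values, role=role)


def grid_search_oracle(angles, diff, a_max=0.02, a_step=1e-5, b_step=0.1):
    """Brute-force minimiser of the fit objective on an (a, b) grid.

    Evaluates sum((diff - a*g_b)^2) = S_dd - 2a*S_dg(b) + a^2*S_gg(b) for
    every grid point, with the sufficient statistics precomputed per
    phase; an exhaustive evaluation, independent of the linear solver.
    """
    a_grid = np.arange(0.0, a_max + a_step / 2, a_step)
    b_grid = np.arange(0.0, 360.0, b_step)
    phi = np.deg2rad(angles)
    g = (np.cos(phi[None, :] - np.deg2rad(b_grid)[:, None])
         - np.cos(np.deg2rad(90.0) - np.deg2rad(b_grid))[:, None])
    s_dg = g @ diff                      # (n_b,)
    s_gg = np.einsum("ij,ij->i", g, g)   # (n_b,)
    obj = (np.sum(diff**2) - 2.0 * a_grid[None, :] * s_dg[:, None]
           + a_grid[None, :] ** 2 * s_gg[:, None])
    ib, ia = np.unravel_index(np.argmin(obj), obj.shape)
    return float(a_grid[ia]), float(b_grid[ib]), float(obj[ib, ia])


class TestCompensationTerm:
    @given(a=amplitudes, b=phases)
    def test_zero_at_90_for_any_parameters(self, a, b):
        assert compensation_term(_fit(a, b), 90.0) == pytest.approx(0.0, abs=1e-15)

    def test_zero_amplitude(self):
        assert compensation_term(_fit(0.0, 123.0), 42.0) == 0.0

    def test_hand_computed_value(self):
        # a=0.004, b=0: a*(cos 180 - cos 90) = -0.004
        assert compensation_term(_fit(0.004, 0.0), 180.0) == pytest.approx(-0.004)


class TestFitArtifact:
    def test_identical_curves_give_zero_amplitude(self, grid):
        ref = _curve(grid, np.ones(len(grid)))
        fit = fit_artifact(ref, ref)
        assert fit.amplitude == 0.0 and fit.phase_deg == 0.0
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-15)

    @given(a=amplitudes, b=phases)
    def test_exact_recovery_without_noise(self, grid, a, b):
        ref_values = np.ones(len(grid))
        measured = ref_values + _term(a, b, grid.angles)
        fit = fit_artifact(_curve(grid, measured), _curve(grid, ref_values))
        assert fit.amplitude == pytest.approx(a, rel=1e-9, abs=1e-12)
        db = (fit.phase_deg - b + 180.0) % 360.0 - 180.0
        assert abs(db) < 1e-6

    def test_agrees_with_grid_search_oracle(self, grid):
        rng = np.random.default_rng(42)
        ref_values = np.ones(len(grid))
        for _ in range(5):
            a, b = rng.uniform(1e-3, 0.015), rng.uniform(0, 360)
            noise = rng.normal(0, 5e-4, len(grid))
            measured = ref_values + _term(a, b, grid.angles) + noise
            fit = fit_artifact(_curve(grid, measured), _curve(grid, ref_values))
            a_o, b_o, obj_o = grid_search_oracle(grid.angles,
                                                 measured - ref_values)
            assert fit.amplitude == pytest.approx(a_o, abs=1e-5)
            db = (fit.phase_deg - b_o + 180.0) % 360.0 - 180.0
            assert abs(db) <= 0.1 + 1e-9
            # the linear solution can never be beaten on the oracle grid
            resid = (measured - ref_values
                     - _term(fit.amplitude, fit.phase_deg, grid.angles))
            assert np.sum(resid**2) <= obj_o + 1e-15

    def test_recovery_under_noise(self, grid):
        # Monte-Carlo tolerance: a within 5e-4, b within 10 deg at SNR 4
        a_true, b_true = 0.004, 210.0
        ref_values = np.ones(len(grid))
        errs_a, errs_b = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            measured = (ref_values + _term(a_true, b_true, grid.angles)
                        + rng.normal(0, 0.001, len(grid)))
            fit = fit_artifact(_curve(grid, measured), _curve(grid, ref_values))
            errs_a.append(fit.amplitude - a_true)
            errs_b.append((fit.phase_deg - b_true + 180.0) % 360.0 - 180.0)
        assert np.all(np.abs(errs_a) < 5e-4)
        assert np.all(np.abs(errs_b) < 10.0)

    def test_window_restricted_fit(self, grid):
        a, b = 0.01, 77.0
        ref_values = np.ones(len(grid))
        measured = ref_values + _term(a, b, grid.angles)
        fit = fit_artifact(_curve(grid, measured), _curve(grid, ref_values),
                           angle_subset=grid.window_angles())
        assert fit.amplitude == pytest.approx(a, rel=1e-9)
        assert fit.fit_angles.size == grid.window_angles().size

    def test_too_few_angles_rejected(self, grid):
        ref = _curve(grid, np.ones(len(grid)))
        with pytest.raises(ValueError, match="at least 3"):
            fit_artifact(ref, ref, angle_subset=[90.0, 100.0])

    @given(a=amplitudes, b=phases)
    def test_residual_never_worse_than_uncompensated(self, grid, a, b):
        rng = np.random.default_rng(0)
        ref_values = np.ones(len(grid))
        measured = (ref_values + _term(a, b, grid.angles)
                    + rng.normal(0, 1e-3, len(grid)))
        fit = fit_artifact(_curve(grid, measured), _curve(grid, ref_values))
        pre = np.sqrt(np.mean((measured - ref_values) ** 2))
        assert fit.residual_rms <= pre + 1e-15


class TestApplyArtifact:
    def test_zero_amplitude_is_identity(self, grid, cs_truth):
        ref = cs_truth.curve(grid)
        out = apply_artifact(ref, _fit(0.0, 0.0))
        assert np.array_equal(out.values, ref.values)
        assert out.role is CurveRole.CS_FIT

    @given(a=amplitudes, b=phases)
    def test_value_at_90_preserved(self, grid, cs_truth, a, b):
        ref = cs_truth.curve(grid)
        out = apply_artifact(ref, _fit(a, b))
        assert out.value_at(90.0) == pytest.approx(ref.value_at(90.0), abs=1e-15)

    def test_fit_then_apply_reproduces_measurement(self, grid, cs_truth):
        ref = cs_truth.curve(grid)
        measured = ref.with_values(ref.values + _term(0.007, 300.0, grid.angles))
        fit = fit_artifact(measured, ref)
        out = apply_artifact(ref, fit, role=CurveRole.CS_ADAPTED)
        assert np.allclose(out.values, measured.values, atol=1e-12)
        assert out.role is CurveRole.CS_ADAPTED

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            _fit(-0.01, 0.0)
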