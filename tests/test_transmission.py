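import numpy as np
import pytest

from ppsatten import (
    CurveRole,
    GantryGrid,
    SimulationConfig,
    TransmissionCurve,
    attenuation,
    estimate_attenuation,
    normalize_cs,
    pps_transmission,
    simulate_session,
    uniform_dose,
)
from ppsatten.series import AngularReadingSeries, UniformDoseSeries


def _series(grid, readings, **kw):
    n = len(grid.angles)
    defaults = dict(angles=grid.angles, readings=readings,
                    temperature_c=20.0, pressure_hpa=1013.25,
                    acquisition_index=np.arange(n))
    defaults.update(kw)
    return AngularReadingSeries(**defaults)


NOISELESS = SimulationConfig(noise_sd=0.0, artifact_amplitude=0.0, drift_total=0.0)


class TestNormalizeCS:
    def test_constant_series_gives_unity(self, grid):
        curve = normalize_cs(_series(grid, np.full(len(grid), 3.7)), grid=grid)
        assert np.allclose(curve.values, 1.0, rtol=1e-14)
        assert curve.role is CurveRole.CS_MEASURED

    def test_direct_ratio(self, grid):
        readings = np.full(len(grid), 2.0)
        i120 = int(np.flatnonzero(grid.angles == 120.0)[0])
        readings[i120] = 2.0 * 0.995
        curve = normalize_cs(_series(grid, readings), grid=grid)
        assert curve.value_at(120.0) == pytest.approx(0.995, rel=1e-14)

    def test_missing_normalisation_angle_rejected(self):
        g = GantryGrid(angles=np.array([100.0, 120.0, 140.0]),
                       forbidden=frozenset())
        with pytest.raises(KeyError):
            normalize_cs(_series(g, np.ones(3)), grid=g)

    def test_noise_free_simulation_recovers_cs_truth(self, grid, cs_truth):
        series = simulate_session(NOISELESS, grid, cs_truth)
        curve = normalize_cs(series, grid=grid)
        assert np.allclose(curve.values, cs_truth.evaluate(grid.angles),
                           atol=1e-13)


class TestUniformDose:
    def test_unity_cs_is_identity(self, grid):
        series = _series(grid, np.full(len(grid), 0.98))
        cs = TransmissionCurve(grid=grid, values=np.ones(len(grid)),
                               role=CurveRole.CS_ADAPTED)
        out = uniform_dose(series, cs)
        assert np.allclose(out.values, 0.98, rtol=1e-14)

    def test_equal_reading_and_cs_give_one(self, grid):
        series = _series(grid, np.full(len(grid), 0.98))
        cs = TransmissionCurve(grid=grid, values=np.full(len(grid), 0.98),
                               role=CurveRole.CS_ADAPTED)
        assert np.allclose(uniform_dose(series, cs).values, 1.0, rtol=1e-14)

    def test_angle_mismatch_rejected(self, grid):
        series = _series(grid, np.ones(len(grid)))
        other = GantryGrid(angles=np.array([90.0, 100.0, 110.0]),
                           forbidden=frozenset())
        cs = TransmissionCurve(grid=other, values=np.ones(3),
                               role=CurveRole.CS_ADAPTED)
        with pytest.raises(ValueError, match="do not match"):
            uniform_dose(series, cs)

    def test_pps_role_rejected(self, grid):
        series = _series(grid, np.ones(len(grid)))
        cs = TransmissionCurve(grid=grid, values=np.ones(len(grid)),
                               role=CurveRole.PPS)
        with pytest.raises(ValueError, match="cryostat-role"):
            uniform_dose(series, cs)

    def test_dividing_out_cs_leaves_pps_only(self, grid, cs_truth, ouh_truth):
        series = simulate_session(NOISELESS, grid, cs_truth, pps_truth=ouh_truth)
        cs = cs_truth.curve(grid, role=CurveRole.CS_ADAPTED)
        out = uniform_dose(series, cs)
        expected = out.values[0] / ouh_truth.transmission(90.0) \
            * ouh_truth.transmission(grid.angles)
        assert np.allclose(out.values, expected, rtol=1e-12)


class TestPPSTransmissionAndAttenuation:
    def test_constant_uniform_gives_unity(self, grid):
        u = UniformDoseSeries(grid=grid, values=np.full(len(grid), 5.0))
        t = pps_transmission(u, grid)
        assert np.allclose(t.values, 1.0, rtol=1e-14)
        assert t.role is CurveRole.PPS

    def test_window_normalised_value(self, grid):
        values = np.ones(len(grid))
        i122 = int(np.flatnonzero(grid.angles == 122.0)[0])
        values[i122] = 0.754
        t = pps_transmission(UniformDoseSeries(grid=grid, values=values), grid)
        a = attenuation(t)
        assert a.value_at(122.0) == pytest.approx(0.246, rel=1e-12)

    def test_scale_invariance(self, grid):
        rng = np.random.default_rng(0)
        values = 1.0 + 0.1 * rng.random(len(grid))
        u1 = UniformDoseSeries(grid=grid, values=values)
        u2 = UniformDoseSeries(grid=grid, values=2.0 * values)
        assert np.allclose(pps_transmission(u1, grid).values,
                           pps_transmission(u2, grid).values, rtol=1e-14)

    def test_attenuation_requires_pps_role(self, grid):
        t = TransmissionCurve(grid=grid, values=np.ones(len(grid)),
                              role=CurveRole.CS_MEASURED)
        with pytest.raises(ValueError, match="PPS"):
            attenuation(t)

    def test_attenuation_values(self, grid):
        values = np.ones(len(grid))
        values[0] = 0.887
        t = TransmissionCurve(grid=grid, values=values, role=CurveRole.PPS)
        assert attenuation(t).values[0] == pytest.approx(0.113, rel=1e-12)

    def test_window_mean_attenuation_is_zero(self, grid, cs_truth, ouh_truth):
        series = simulate_session(SimulationConfig(seed=3), grid, cs_truth,
                                  pps_truth=ouh_truth)
        curve, _ = estimate_attenuation(series, cs_truth.curve(grid), grid)
        window_vals = curve.values[grid.window_mask()]
        assert np.mean(window_vals) == pytest.approx(0.0, abs=1e-14)


class TestEndToEnd:
    @pytest.mark.parametrize("site", ["OUH-like", "UAS-like"])
    def test_noise_free_round_trip_recovers_truth(self, grid, cs_truth, site):
        from ppsatten import make_default_anchors

        truth = make_default_anchors(site)
        series = simulate_session(NOISELESS, grid, cs_truth, pps_truth=truth)
        est, fit = estimate_attenuation(series, cs_truth.curve(grid), grid)
        assert fit.amplitude == 0.0
        assert np.max(np.abs(est.values - truth.evaluate(grid.angles))) < 1e-12

    def test_global_rescaling_cancels(self, grid, cs_truth, ouh_truth):
        series = simulate_session(SimulationConfig(seed=11), grid, cs_truth,
                                  pps_truth=ouh_truth)
        scaled = AngularReadingSeries(
            angles=series.angles, readings=3.21 * series.readings,
            temperature_c=series.temperature_c, pressure_hpa=series.pressure_hpa,
            acquisition_index=series.acquisition_index,
            configuration=series.configuration)
        ref = cs_truth.curve(grid)
        a1, _ = estimate_attenuation(series, ref, grid)
        a2, _ = estimate_attenuation(scaled, ref, grid)
        assert np.allclose(a1.values, a2.values, atol=1e-14)
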