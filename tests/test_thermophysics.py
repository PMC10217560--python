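"""Heat-capacity determination and regression models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmetex.synthetic_data import simulate_cp_scans
from hmetex.thermophysics import (
    CpMlrModel,
    CpPoint,
    cp_from_heatflow,
    fit_cp_linear,
    fit_cp_mlr,
    predict_cp,
    water_cp_literature,
    water_extrapolation_error,
)


class TestCpFromHeatflow:
    def test_water_identity(self):
        """A sample that is literally water, on a perfect instrument, returns
        the literature water cp (correction factor k == 1)."""
        sample, blank, water = simulate_cp_scans(water_cp_literature, 1.0)
        pts = cp_from_heatflow(sample, blank, water)
        t = np.array([p.temperature_C for p in pts])
        cp = np.array([p.cp_J_per_kgK for p in pts])
        assert np.allclose(cp, water_cp_literature(t), rtol=1e-12)

    def test_blank_equals_sample_gives_zero(self):
        sample, blank, water = simulate_cp_scans(water_cp_literature, 1.0)
        pts = cp_from_heatflow(blank, blank, water)
        assert all(p.cp_J_per_kgK == pytest.approx(0.0, abs=1e-12) for p in pts)

    def test_reference_bias_removed(self):
        """A +2% instrument gain is cancelled by the water-reference
        correction; the generating cp line is recovered to numerical
        precision."""
        cp_true = lambda t: 3000.0 + 5.0 * np.asarray(t)
        sample, blank, water = simulate_cp_scans(cp_true, 0.6,
                                                 instrument_gain=1.02)
        pts = cp_from_heatflow(sample, blank, water)
        for p in pts:
            assert p.cp_J_per_kgK == pytest.approx(cp_true(p.temperature_C),
                                                   abs=1e-9)

    @pytest.mark.parametrize("gain", [0.9, 1.0, 1.1, 2.0])
    def test_calibration_roundtrip_any_gain(self, gain):
        cp_true = lambda t: 2800.0 + 4.0 * np.asarray(t)
        sample, blank, water = simulate_cp_scans(cp_true, 0.65,
                                                 instrument_gain=gain)
        pts = cp_from_heatflow(sample, blank, water)
        for p in pts[::10]:
            assert p.cp_J_per_kgK == pytest.approx(cp_true(p.temperature_C),
                                                   rel=1e-9)

    def test_non_overlapping_ranges_rejected(self):
        s1, b1, w1 = simulate_cp_scans(water_cp_literature, 1.0,
                                       T_range=(40.0, 70.0))
        s2, _, _ = simulate_cp_scans(water_cp_literature, 1.0,
                                     T_range=(80.0, 115.0))
        with pytest.raises(ValueError, match="overlap"):
            cp_from_heatflow(s2, b1, w1)


class TestLinearFit:
    def test_exact_line_recovery(self):
        t = np.linspace(40, 115, 30)
        pts = [CpPoint(ti, 0.6, 3103.09 + 4.6319 * ti) for ti in t]
        m = fit_cp_linear(pts)
        assert m.intercept == pytest.approx(3103.09, abs=1e-9)
        assert m.slope_per_degC == pytest.approx(4.6319, abs=1e-9)
        assert m.valid_T_range == (40.0, 115.0)

    def test_flat_data_zero_slope(self):
        pts = [CpPoint(40.0, 0.6, 3200.0), CpPoint(115.0, 0.6, 3200.0)]
        m = fit_cp_linear(pts)
        assert m.slope_per_degC == pytest.approx(0.0, abs=1e-12)
        assert m.intercept == pytest.approx(3200.0)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(7)
        t = np.linspace(40, 115, 200)
        cp = 3100.0 + 4.5 * t + rng.normal(0, 10.0, t.size)
        m = fit_cp_linear([CpPoint(ti, 0.6, ci) for ti, ci in zip(t, cp)])
        se_slope = 10.0 / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(m.slope_per_degC - 4.5) < 3 * se_slope

    def test_identical_temperatures_rejected(self):
        pts = [CpPoint(50.0, 0.6, 3000.0 + i) for i in range(5)]
        with pytest.raises(ValueError, match="rank"):
            fit_cp_linear(pts)

    def test_mixed_water_fractions_rejected(self):
        pts = [CpPoint(40.0, 0.6, 3000.0), CpPoint(50.0, 0.7, 3100.0),
               CpPoint(60.0, 0.6, 3200.0)]
        with pytest.raises(ValueError, match="water"):
            fit_cp_linear(pts)


def _plane_points(y0, a, b, noise_sd=0.0, n_t=10, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    for xw in (0.6, 0.65, 0.7):
        for t in np.linspace(40, 115, n_t):
            cp = y0 + a * xw + b * t
            if noise_sd:
                cp += rng.normal(0, noise_sd)
            pts.append(CpPoint(float(t), xw, float(cp)))
    return pts


class TestMlrFit:
    def test_noiseless_plane_recovery(self):
        m = fit_cp_mlr(_plane_points(1675.38, 2408.56, 4.6196))
        assert m.y0 == pytest.approx(1675.38, abs=1e-9)
        assert m.a_Xw == pytest.approx(2408.56, abs=1e-9)
        assert m.b_T == pytest.approx(4.6196, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_surface(self):
        pts = [CpPoint(t, xw, 3333.0)
               for xw in (0.6, 0.7) for t in (40.0, 80.0, 115.0)]
        m = fit_cp_mlr(pts)
        assert m.a_Xw == pytest.approx(0.0, abs=1e-9)
        assert m.b_T == pytest.approx(0.0, abs=1e-9)
        assert m.y0 == pytest.approx(3333.0)

    def test_residual_standard_error_recovery(self):
        m = fit_cp_mlr(_plane_points(1675.38, 2408.56, 4.6196,
                                     noise_sd=24.16, n_t=100, seed=11))
        assert m.standard_error == pytest.approx(24.16, rel=0.15)

    def test_rank_deficient_rejected(self):
        pts = [CpPoint(40.0, 0.6, 3000.0), CpPoint(50.0, 0.6, 3050.0),
               CpPoint(60.0, 0.6, 3100.0), CpPoint(70.0, 0.6, 3150.0)]
        with pytest.raises(ValueError):
            fit_cp_mlr(pts)


class TestPredict:
    def test_printed_polynomial_evaluations(self, cp_models):
        assert predict_cp(cp_models["SPC Procon"], 0.6, 20.0) == \
            pytest.approx(3212.908, abs=1e-9)
        # 1867.48 + 2393.64*0.6 + 2.6710*72
        assert predict_cp(cp_models["SPI Wilpro"], 0.6, 72.0,
                          warn_extrapolation=False) == \
            pytest.approx(3495.976, abs=1e-9)

    def test_origin_returns_intercept(self, cp_models):
        for m in cp_models.values():
            assert predict_cp(m, 0.0, 0.0, warn_extrapolation=False) == \
                pytest.approx(m.y0)

    def test_out_of_box_warns(self, cp_models):
        with pytest.warns(UserWarning, match="validity box"):
            predict_cp(cp_models["SPC Procon"], 1.0, 150.0)

    @settings(derandomize=True, max_examples=50)
    @given(xw=st.floats(0.0, 1.0), t1=st.floats(0.0, 200.0),
           t2=st.floats(0.0, 200.0))
    def test_affine_in_temperature(self, cp_models, xw, t1, t2):
        m = cp_models["PPI Pisane"]
        lhs = predict_cp(m, xw, t1, False) + predict_cp(m, xw, t2, False)
        mid = 2 * predict_cp(m, xw, (t1 + t2) / 2, False)
        assert lhs == pytest.approx(mid, rel=1e-12, abs=1e-9)

    def test_monotone_in_water_and_temperature(self, cp_models):
        """All packaged models have positive water and temperature slopes,
        so cp rises monotonically across the validity box."""
        for m in cp_models.values():
            assert m.a_Xw > 0 and m.b_T > 0
            for xw in np.linspace(0.6, 0.7, 5):
                along_t = predict_cp(m, xw, np.linspace(40, 115, 9), False)
                assert np.all(np.diff(along_t) > 0)
            for t in np.linspace(40, 115, 5):
                along_xw = predict_cp(m, np.linspace(0.6, 0.7, 9), t, False)
                assert np.all(np.diff(along_xw) > 0)


class TestWaterExtrapolation:
    def test_zero_error_when_model_matches_water(self):
        m = CpMlrModel(y0=0.0, a_Xw=water_cp_literature(60.0), b_T=0.0)
        assert water_extrapolation_error(m, 60.0) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_bias_recovered(self):
        lit40 = water_cp_literature(40.0)
        m = CpMlrModel(y0=0.0, a_Xw=1.095 * lit40, b_T=0.0)
        assert water_extrapolation_error(m, 40.0) == pytest.approx(0.095, abs=1e-12)

    def test_error_grows_with_temperature_for_steep_models(self, cp_models):
        """When the model's temperature slope exceeds the (nearly flat)
        water-cp slope, the pure-water extrapolation error grows with T."""
        m = cp_models["SPC Procon"]
        errs = water_extrapolation_error(m, np.linspace(40, 115, 16))
        assert np.all(np.diff(errs) > 0)
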