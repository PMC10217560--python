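"""Structuring index, cutting-strength profiles and class statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hmetex.synthetic_data import simulate_ssf_profile
from hmetex.texture_metrics import (
    class_statistics,
    fit_quadratic_profile,
    si_parameter_regressions,
    structuring_index,
    structuring_index_from_measurements,
    threshold_screen,
)


class TestStructuringIndex:
    def test_equal_forces(self):
        assert structuring_index(2.0, 2.0).SI == pytest.approx(1.0)

    def test_direct_ratio(self):
        assert structuring_index(1.54, 1.0).SI == pytest.approx(1.54)

    def test_nonpositive_force_rejected(self):
        with pytest.raises(ValueError):
            structuring_index(0.0, 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(fm=st.floats(0.1, 100.0), fo=st.floats(0.1, 100.0),
           s=st.floats(0.01, 1000.0))
    def test_scale_invariance(self, fm, fo, s):
        assert structuring_index(s * fm, s * fo).SI == \
            pytest.approx(structuring_index(fm, fo).SI, rel=1e-12)

    def test_generator_ratio_recovered(self):
        """Noise-free parabolic specimens built for SI = 1.64 return
        exactly that index."""
        meas = simulate_ssf_profile(1.64, noise_sd_N=0.0)
        assert structuring_index_from_measurements(meas).SI == \
            pytest.approx(1.64, abs=1e-12)


class TestQuadraticProfile:
    def test_exact_parabola(self):
        pts = [(x, 10.0 - 0.01 * (x - 30.0) ** 2) for x in (0, 10, 20, 30, 40, 60)]
        fit = fit_quadratic_profile(pts)
        assert fit.c2 == pytest.approx(-0.01, abs=1e-12)
        assert fit.vertex_x_mm == pytest.approx(30.0, abs=1e-9)
        assert fit.vertex_force_N == pytest.approx(10.0, abs=1e-9)
        assert fit.parabolic

    def test_flat_profile_not_parabolic(self):
        pts = [(x, 5.0) for x in (0, 20, 40, 60)]
        fit = fit_quadratic_profile(pts)
        assert fit.c2 == pytest.approx(0.0, abs=1e-12)
        assert not fit.parabolic

    def test_noisy_vertex_recovery(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 60, 25)
        y = 12.0 - 0.008 * (x - 30.0) ** 2 + rng.normal(0, 0.6, x.size)
        fit = fit_quadratic_profile(list(zip(x, y)))
        assert fit.vertex_x_mm == pytest.approx(30.0, abs=3.0)

    def test_parabolic_flag_tracks_generated_structure(self):
        for si in (1.0, 1.2, 1.64):
            meas = simulate_ssf_profile(si)
            pts = [(m.x_mm, m.cutting_strength_N) for m in meas
                   if m.orientation == "longitudinal"]
            fit = fit_quadratic_profile(pts)
            assert fit.parabolic == (si > 1.0)

    def test_si_grows_with_curvature(self):
        """For a downward parabola the specimen-based index exceeds 1 and
        grows with |c2| * (half-width)^2."""
        sis = []
        for si_target in (1.1, 1.3, 1.6):
            meas = simulate_ssf_profile(si_target)
            sis.append(structuring_index_from_measurements(meas).SI)
        assert all(s > 1 for s in sis)
        assert sis == sorted(sis)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic_profile([(10.0, 1.0), (10.0, 1.1),
                                   (20.0, 1.2), (20.0, 1.3)])


class TestClassStatistics:
    def test_reference_poorly_textured_moments(self, screening_runs):
        """The poorly-textured group of the screening campaign has SI
        mean 1.25 and sample SD 0.11 at two decimals."""
        stats = class_statistics(screening_runs)
        row = stats["summary"].set_index("texture_label").loc["poorly-textured"]
        assert round(row["mean"], 2) == 1.25
        assert round(row["sd"], 2) == 0.11
        assert row["n"] == 6

    def test_well_textured_separates(self, screening_runs):
        """One-way ANOVA across the three sensory classes is significant,
        and the well-textured class differs from both others."""
        stats = class_statistics(screening_runs)
        assert stats["anova_p"] < 0.05
        pw = stats["pairwise"]
        well = pw[(pw["group1"] == "well-textured")
                  | (pw["group2"] == "well-textured")]
        assert bool(well["reject"].all())

    def test_identical_classes_not_significant(self, screening_runs):
        vals = [1.2, 1.3, 1.25, 1.28]
        import copy
        runs = []
        for label in ("textured", "well-textured"):
            for i, v in enumerate(vals):
                r = copy.copy(screening_runs[0])
                r.run_id = f"{label}-{i}"
                r.texture_label = label
                r.structuring_index = v
                runs.append(r)
        stats = class_statistics(runs)
        assert stats["anova_F"] == pytest.approx(0.0, abs=1e-9)
        assert stats["anova_p"] > 0.9

    def test_shifted_classes_significant(self, screening_runs):
        import copy
        rng = np.random.default_rng(5)
        runs = []
        for label, mu in (("textured", 1.2), ("well-textured", 1.5)):
            for i in range(20):  # shift = 3 SD with sd = 0.1
                r = copy.copy(screening_runs[0])
                r.run_id = f"{label}-{i}"
                r.texture_label = label
                r.structuring_index = float(rng.normal(mu, 0.1))
                runs.append(r)
        assert class_statistics(runs)["anova_p"] < 0.05

    def test_single_class_rejected(self, screening_runs):
        subset = [r for r in screening_runs
                  if r.texture_label == "textured"]
        with pytest.raises(ValueError):
            class_statistics(subset)

    def test_means_match_independent_resummation(self, screening_runs):
        """Group means agree with a direct arithmetic re-summation over
        the fixture rows (independent of pandas groupby)."""
        stats = class_statistics(screening_runs)
        for label in ("well-textured", "textured", "poorly-textured"):
            vals = [r.structuring_index for r in screening_runs
                    if r.texture_label == label
                    and r.structuring_index is not None]
            expected = sum(vals) / len(vals)
            row = stats["summary"].set_index("texture_label").loc[label]
            assert row["mean"] == pytest.approx(expected, rel=1e-12)


class TestRegressions:
    def test_collinear_data_r2_one(self, screening_runs):
        import copy
        runs = []
        for i, t in enumerate(np.linspace(90, 140, 10)):
            r = copy.copy(screening_runs[0])
            r.run_id = str(i)
            r.material_temperature_Tin_C = float(t)
            r.structuring_index = 0.5 + 0.008 * float(t)
            runs.append(r)
        out = si_parameter_regressions(runs)
        assert out["si_vs_temperature"]["r_squared"] == pytest.approx(1.0,
                                                                      abs=1e-12)

    def test_independent_predictor_near_zero_r2(self, screening_runs):
        import copy
        rng = np.random.default_rng(17)
        runs = []
        for i in range(50):
            r = copy.copy(screening_runs[0])
            r.run_id = str(i)
            r.material_temperature_Tin_C = float(rng.uniform(90, 140))
            r.structuring_index = float(rng.normal(1.3, 0.15))
            runs.append(r)
        out = si_parameter_regressions(runs)
        assert out["si_vs_temperature"]["r_squared"] < 0.1

    def test_reference_temperature_correlation(self, screening_runs):
        """SI against material temperature over the 21 index-bearing
        screening runs explains roughly 60% of the variance."""
        out = si_parameter_regressions(screening_runs)
        assert 0.55 <= out["si_vs_temperature"]["r_squared"] <= 0.70
        assert out["si_vs_temperature"]["n"] == 21
        assert out["si_vs_temperature"]["slope"] > 0

    def test_two_predictor_fits_increase_r2(self, screening_runs):
        out = si_parameter_regressions(screening_runs)
        simple = out["si_vs_temperature"]["r_squared"]
        # pressure is recorded for every SI-bearing run, so adding it can
        # only raise R^2; SME regression runs on the measurable subset
        assert out["si_vs_temperature_pressure"]["r_squared"] >= simple
        assert 0.5 < out["si_vs_temperature_sme"]["r_squared"] <= 1.0


class TestThresholdScreen:
    def test_well_textured_minima(self, screening_runs):
        df = threshold_screen(screening_runs).set_index("texture_label")
        well = df.loc["well-textured"]
        assert well["min_material_temperature_C"] == pytest.approx(117.76)
        assert well["min_pressure_bar"] == pytest.approx(9.69)
        assert well["min_SME_Wh_per_kg"] == pytest.approx(9.71)
        assert well["min_material_temperature_C_above_threshold"]
        assert well["min_pressure_bar_above_threshold"]
        assert well["min_SME_Wh_per_kg_above_threshold"]

    def test_unmeasured_sme_excluded(self, screening_runs):
        df = threshold_screen(screening_runs).set_index("texture_label")
        # poorly-textured group contains SME-unmeasurable runs; the minimum
        # must come from a measured value, not an imputed zero
        assert df.loc["poorly-textured", "min_SME_Wh_per_kg"] > 0

    def test_absent_class_reported_missing(self, screening_runs):
        subset = [r for r in screening_runs if r.texture_label == "textured"]
        df = threshold_screen(subset)
        assert set(df["texture_label"]) == {"textured"}
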