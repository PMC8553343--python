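"""Calibration math: Förster–Hoffmann fit, titration fit, LOD, inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marginscreen import (
    EmissionSeries,
    SpectraConfig,
    blank_sigma,
    compute_lod,
    fit_forster_hoffmann,
    fit_titration,
    fold_enhancement,
    gen_viscosity_series,
    invert_viscosity,
)
from marginscreen.photophysics import read_emission_csv, write_emission_csv


def ols_oracle(x, y):
    """Normal-equations least squares, independent of scipy."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * (y * y).sum() - sy * sy))
    return slope, intercept, r


class TestForsterHoffmann:
    def test_exact_decade_line(self):
        s = EmissionSeries("viscosity", ((1, 10), (10, 100), (100, 1000)))
        fit = fit_forster_hoffmann(s)
        assert fit.slope_x == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept_c == pytest.approx(1.0, abs=1e-12)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_generator_recovery(self):
        cfg = SpectraConfig(rel_noise=0.0, seed=1)
        fit = fit_forster_hoffmann(gen_viscosity_series(cfg))
        assert fit.slope_x == pytest.approx(cfg.slope_x, abs=1e-9)
        assert fit.intercept_c == pytest.approx(cfg.intercept_c, abs=1e-9)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        cfg = SpectraConfig(rel_noise=0.01, seed=1)
        series = gen_viscosity_series(cfg)
        fit = fit_forster_hoffmann(series)
        slope, intercept, r = ols_oracle(np.log10(series.conditions),
                                         np.log10(series.intensities))
        assert fit.slope_x == pytest.approx(slope, abs=1e-10)
        assert fit.intercept_c == pytest.approx(intercept, abs=1e-10)
        assert fit.pearson_r == pytest.approx(r, abs=1e-10)
        # slope recovered within the advertised tolerance at 1% noise
        assert fit.slope_x == pytest.approx(cfg.slope_x, abs=0.02)

    @pytest.mark.parametrize("points, err", [
        (((1, 10),), "at least 2"),
        (((1, 10), (1, 20)), "degenerate"),
        (((1, 0), (10, 100)), "positive"),
    ])
    def test_invalid_inputs(self, points, err):
        s = EmissionSeries("viscosity", points)
        with pytest.raises(ValueError, match=err):
            fit_forster_hoffmann(s)

    def test_nonpositive_viscosity_rejected_at_construction(self):
        with pytest.raises(ValueError, match="positive"):
            EmissionSeries("viscosity", ((0.0, 10.0), (1.0, 20.0)))


class TestInvertViscosity:
    def test_inverse_of_exact_line(self):
        fit = fit_forster_hoffmann(
            EmissionSeries("viscosity", ((1, 10), (10, 100), (100, 1000))))
        assert invert_viscosity(fit, 100.0) == pytest.approx(10.0, abs=1e-9)
        # intensity 10^c maps to eta = 1
        assert invert_viscosity(fit, 10.0 ** fit.intercept_c) == pytest.approx(1.0)

    def test_round_trip_identity(self, rng):
        fit = fit_forster_hoffmann(gen_viscosity_series(SpectraConfig(seed=5)))
        etas = rng.uniform(0.5, 2000.0, size=100)
        for eta in etas:
            back = invert_viscosity(fit, float(fit.predict_intensity(eta)))
            assert back == pytest.approx(eta, rel=1e-9)

    def test_errors(self):
        from marginscreen.photophysics import CalibrationFit
        flat = CalibrationFit(slope_x=0.0, intercept_c=1.0, pearson_r=0.0, n=3)
        with pytest.raises(ValueError, match="non-invertible"):
            invert_viscosity(flat, 10.0)
        ok = CalibrationFit(slope_x=1.0, intercept_c=1.0, pearson_r=1.0, n=3)
        with pytest.raises(ValueError, match="positive"):
            invert_viscosity(ok, 0.0)


class TestTitration:
    def test_noise_free_slope(self):
        concs = np.linspace(0.5, 9.0, 10)
        s = EmissionSeries("titration", tuple((c, 11166.424 * c) for c in concs))
        fit = fit_titration(s)
        assert fit.slope_k == pytest.approx(11166.424, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_two_points_exact_interpolation(self):
        fit = fit_titration(EmissionSeries("titration", ((1.0, 5.0), (3.0, 11.0))))
        assert fit.slope_k == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(2.0)

    def test_noisy_fit_matches_oracle_and_configured_slope(self):
        from marginscreen import gen_ntr_titration
        cfg = SpectraConfig(seed=2)
        series, _ = gen_ntr_titration(cfg)
        fit = fit_titration(series)
        slope, intercept, r = ols_oracle(series.conditions, series.intensities)
        assert fit.slope_k == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.slope_k == pytest.approx(cfg.titration_slope_k, rel=0.02)

    def test_zero_concentration_variance_rejected(self):
        s = EmissionSeries("titration", ((2.0, 5.0), (2.0, 7.0)))
        with pytest.raises(ValueError, match="degenerate"):
            fit_titration(s)


class TestBlankSigmaAndLod:
    def test_blank_sigma_hand_cases(self):
        assert blank_sigma([4.0, 4.0, 4.0]) == 0.0
        assert blank_sigma([1.0, 2.0, 3.0]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            blank_sigma([1.0])

    def test_blank_sigma_monte_carlo(self, rng):
        draws = rng.normal(0.0, 77.883, size=1000)
        assert blank_sigma(draws) == pytest.approx(77.883, rel=0.05)

    def test_lod_paper_inputs_display(self):
        lod = compute_lod(11166.424, 77.883)
        assert lod.display_ng_per_ml() == "20.9"
        assert lod.lod_ng_per_ml == pytest.approx(1000 * lod.lod_ug_per_ml)

    @pytest.mark.parametrize("k, sigma, expect", [(3.0, 1.0, 1.0), (5.0, 0.0, 0.0)])
    def test_lod_unit_cases(self, k, sigma, expect):
        assert compute_lod(k, sigma).lod_ug_per_ml == pytest.approx(expect)

    @given(k=st.floats(1e-3, 1e6), sigma=st.floats(0, 1e6),
           scale=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_lod_homogeneous_in_common_scale(self, k, sigma, scale):
        a = compute_lod(k, sigma).lod_ug_per_ml
        b = compute_lod(k * scale, sigma * scale).lod_ug_per_ml
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)

    def test_lod_invalid_slope(self):
        with pytest.raises(ValueError):
            compute_lod(0.0, 1.0)


class TestFoldEnhancement:
    def test_constant_series_is_unity(self):
        s = EmissionSeries("viscosity", ((1, 7.0), (10, 7.0), (100, 7.0)))
        assert fold_enhancement(s) == pytest.approx(1.0)

    def test_default_generator_hits_18_fold(self):
        s = gen_viscosity_series(SpectraConfig(rel_noise=0.0))
        assert fold_enhancement(s) == pytest.approx(18.0, abs=1e-9)

    def test_ratio_ignores_point_order(self):
        pts = ((945.0, 180.0), (1.2, 10.0), (50.0, 60.0))
        assert fold_enhancement(EmissionSeries("viscosity", pts)) == pytest.approx(18.0)


def test_emission_csv_round_trip(tmp_path):
    s = gen_viscosity_series(SpectraConfig(rel_noise=0.01, seed=9))
    p = tmp_path / "series.csv"
    write_emission_csv(s, p)
    back = read_emission_csv(p)
    assert back.kind == s.kind
    assert back.wavelength_nm == s.wavelength_nm
    np.testing.assert_array_equal(back.conditions, s.conditions)
    np.testing.assert_array_equal(back.intensities, s.intensities)
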