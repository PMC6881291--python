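"""Film dosimetry: pixel correction, calibration, ROI, uncertainty, synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtsim.errors import AnalysisError, ConfigurationError
from mrtsim.film import (CalibrationCurve, FilmImage, UncertaintyBudget,
                         combine_uncertainty, dose_from_pixel, fit_calibration,
                         pixel_correct, read_tiff, roi_mean, synth_film,
                         write_tiff)


def _img(values, role="post"):
    return FilmImage(np.asarray(values, dtype=np.uint8), role=role)


class TestPixelCorrect:
    def test_identical_images_zero(self):
        a = _img(np.full((8, 8), 120))
        b = _img(np.full((8, 8), 120), role="pre")
        assert np.all(pixel_correct(a, b) == 0.0)

    def test_simple_difference(self):
        post = _img(np.full((4, 4), 200))
        pre = _img(np.full((4, 4), 180), role="pre")
        assert np.all(pixel_correct(post, pre) == 20.0)

    def test_absolute_value_symmetry(self):
        post = _img(np.full((4, 4), 100))
        pre = _img(np.full((4, 4), 120), role="pre")
        assert np.all(pixel_correct(post, pre) == 20.0)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 255), st.integers(0, 255))
    def test_symmetric_in_arguments(self, a, b):
        pa = _img(np.full((3, 3), a))
        pb = _img(np.full((3, 3), b), role="pre")
        qa = _img(np.full((3, 3), b))
        qb = _img(np.full((3, 3), a), role="pre")
        assert np.array_equal(pixel_correct(pa, pb), pixel_correct(qa, qb))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_correct(_img(np.zeros((4, 4))), _img(np.zeros((5, 4)), role="pre"))

    def test_white_field_division(self):
        wf = np.linspace(0.8, 1.2, 16).reshape(4, 4)
        post = _img(np.round(100 * wf))
        pre = _img(np.round(50 * wf), role="pre")
        corrected = pixel_correct(post, pre, white_field=wf)
        assert np.all(np.abs(corrected - 50.0) < 1.0)  # quantisation only


class TestCalibrationCurve:
    def test_constant_term_at_zero_pixel(self):
        dose, ok = dose_from_pixel(0.0, CalibrationCurve.default())
        assert dose == pytest.approx(20.5)

    def test_identity_polynomial(self):
        curve = CalibrationCurve(0.0, 0.0, 0.0, 1.0, 0.0, dose_range=(0.0, 255.0))
        dose, ok = dose_from_pixel(5.0, curve)
        assert dose == 5.0 and ok

    def test_out_of_range_flagged(self):
        curve = CalibrationCurve.default()
        _, ok = dose_from_pixel(curve.inverse(0.3), curve)
        assert ok
        # beyond the 64 Gy calibration ceiling the evaluation is unreliable
        dose_hi, ok_hi = dose_from_pixel(200.0, curve)
        assert dose_hi > 64.0 and not ok_hi
        # a saturated-black pixel value maps below the 0.25 Gy floor
        p_floor = curve.inverse(0.25)
        dose_lo, ok_lo = dose_from_pixel(p_floor - 3.0, curve)
        assert dose_lo < 0.25 and not ok_lo

    def test_numerical_inversion_round_trip(self):
        curve = CalibrationCurve.default()
        doses = np.linspace(0.3, 63.0, 40)
        back = curve(curve.inverse(doses))
        assert np.allclose(back, doses, atol=1e-6)

    def test_json_round_trip(self, tmp_path):
        curve = CalibrationCurve.default()
        curve.to_json(tmp_path / "curve.json")
        back = CalibrationCurve.from_json(tmp_path / "curve.json")
        assert np.allclose(back.coefficients, curve.coefficients)
        assert back.dose_range == curve.dose_range


class TestFitCalibration:
    def test_recovers_known_quartic(self):
        truth = CalibrationCurve.default()
        p = np.linspace(40.0, 160.0, 12)
        curve, resid = fit_calibration(truth(p), p)
        assert np.allclose(curve.coefficients, truth.coefficients, rtol=1e-6, atol=1e-10)
        assert np.max(np.abs(resid)) < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(AnalysisError):
            fit_calibration([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])

    def test_duplicate_dose_points_still_fit(self):
        p = np.array([40.0, 50.0, 60.0, 60.0, 80.0, 100.0, 120.0])
        d = CalibrationCurve.default()(p)
        d[3] = d[2]
        curve, _ = fit_calibration(d, p)
        assert np.all(np.isfinite(curve.coefficients))

    def test_noisy_points_predict_within_three_percent(self):
        """1% pixel noise on the production curve: the relative-weighted fit
        predicts doses to ~3% (the low-dose toe of the quartic carries little
        pixel information, so the 1 Gy edge is checked via the median)."""
        truth = CalibrationCurve.default()
        rng = np.random.default_rng(12)
        doses = np.linspace(0.25, 64.0, 40)
        p = truth.inverse(doses) * (1.0 + 0.01 * rng.standard_normal(40))
        curve, _ = fit_calibration(doses, p, weights="relative")
        check = np.linspace(1.0, 60.0, 50)
        rel = np.abs(curve(truth.inverse(check)) / check - 1.0)
        assert np.median(rel) < 0.03
        assert np.all(rel[check >= 10.0] < 0.03)


class TestUncertaintyBudget:
    def test_film_protocol_budget(self):
        combined, expanded = combine_uncertainty(UncertaintyBudget.film_protocol())
        assert combined == pytest.approx(5.2, abs=0.05)
        assert expanded == pytest.approx(10.4, abs=0.05)

    def test_single_component(self):
        c, e = combine_uncertainty(UncertaintyBudget([("x", 3.0, "A")], coverage_factor=2.0))
        assert (c, e) == (3.0, 6.0)

    def test_all_zero(self):
        c, e = combine_uncertainty(UncertaintyBudget([("x", 0.0, "A"), ("y", 0.0, "B")]))
        assert (c, e) == (0.0, 0.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.0, 50.0), min_size=1, max_size=8))
    def test_permutation_invariant_and_monotone(self, values):
        budget = UncertaintyBudget([(f"c{i}", v, "A") for i, v in enumerate(values)])
        shuffled = UncertaintyBudget([(f"c{i}", v, "A") for i, v in enumerate(reversed(values))])
        assert combine_uncertainty(budget) == pytest.approx(combine_uncertainty(shuffled), rel=1e-12)
        bigger = UncertaintyBudget([("c0", values[0] + 1.0, "A")]
                                   + [(f"c{i}", v, "A") for i, v in enumerate(values[1:], 1)])
        assert combine_uncertainty(bigger)[0] >= combine_uncertainty(budget)[0]


class TestRoiMean:
    def test_constant_image(self):
        img = _img(np.full((2000, 2000), 55))
        assert roi_mean(img, "circle") == 55.0
        assert roi_mean(img, "rectangle") == 55.0

    def test_roi_outside_image_rejected(self):
        img = _img(np.full((100, 100), 10))  # 0.7 mm across at 7 um pixels
        with pytest.raises(ValueError):
            roi_mean(img, "circle", size_mm=10.0)

    def test_circle_and_rectangle_agree_on_radial_image(self):
        n = 2200
        r = np.hypot(*np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2))
        img = _img(np.clip(200 - r * 0.05, 0, 255))
        c = roi_mean(img, "circle", size_mm=10.0)
        s = roi_mean(img, "rectangle", size_mm=10.0 * np.sqrt(np.pi) / 2)
        # equal-area shapes on a radially symmetric image agree closely
        assert c == pytest.approx(s, rel=0.01)


class TestSynthFilm:
    def test_round_trip_within_quantisation(self):
        """Noiseless synthetic film returns the dose map through the pipeline."""
        curve = CalibrationCurve.default()
        dose_map = np.linspace(2.0, 60.0, 64).reshape(8, 8)
        pre, post = synth_film(dose_map, curve, granularity_noise_pct=0.0, seed=1)
        corrected = pixel_correct(post, pre)
        dose, ok = dose_from_pixel(corrected, curve)
        p = curve.inverse(dose_map)
        slope = np.abs(np.polyval(np.polyder(curve.coefficients), p))
        assert np.all(np.abs(dose - dose_map) <= 0.5 * slope + 1e-9)
        assert ok.all()

    def test_noise_controls_roi_coefficient_of_variation(self):
        curve = CalibrationCurve.default()
        pre, post = synth_film(np.full((600, 600), 30.0), curve,
                               granularity_noise_pct=3.6, seed=4)
        corrected = pixel_correct(post, pre)
        cov = corrected.std() / corrected.mean()
        assert cov == pytest.approx(0.036, abs=0.004)

    def test_seed_reproducibility(self):
        curve = CalibrationCurve.default()
        a = synth_film(np.full((32, 32), 20.0), curve, 3.6, seed=9)
        b = synth_film(np.full((32, 32), 20.0), curve, 3.6, seed=9)
        assert np.array_equal(a[1].pixels, b[1].pixels)
        assert np.array_equal(a[0].pixels, b[0].pixels)

    def test_illumination_field_corrected_by_white_field(self):
        curve = CalibrationCurve.default()
        yy, xx = np.meshgrid(np.linspace(-1, 1, 64), np.linspace(-1, 1, 64))
        illum = 1.0 - 0.15 * (xx**2 + yy**2)  # radial roll-off of the lamp
        dose_map = np.full((64, 64), 25.0)
        pre, post = synth_film(dose_map, curve, 0.0, illumination=illum, seed=2)
        corrected = pixel_correct(post, pre, white_field=illum)
        dose, _ = dose_from_pixel(corrected, curve)
        assert np.median(np.abs(dose - 25.0)) < 0.5


def test_end_to_end_microbeam_film_within_expanded_uncertainty():
    """Synthetic microbeam film analysis recovers the peak dose within the
    10.4% expanded uncertainty of the protocol."""
    from conftest import make_comb_profile
    from mrtsim.dosimetry import mb_metrics

    curve = CalibrationCurve.default()
    y, v = make_comb_profile(peak=25.0, valley=0.8, step_um=7.0)
    dose_map = np.tile(v, (200, 1))
    pre, post = synth_film(dose_map, curve, granularity_noise_pct=3.6, seed=6)
    corrected = pixel_correct(post, pre)
    dose, _ = dose_from_pixel(corrected.mean(axis=0), curve)
    m = mb_metrics((y, dose))
    assert abs(m.peak_dose - 25.0) / 25.0 < 0.104


def test_blue_channel_refused():
    with pytest.raises(ConfigurationError):
        FilmImage(np.zeros((4, 4), dtype=np.uint8), channel="blue")


def test_tiff_round_trip(tmp_path):
    curve = CalibrationCurve.default()
    pre, post = synth_film(np.full((16, 16), 10.0), curve, 1.0, seed=3)
    write_tiff(post, tmp_path / "post.tif")
    back = read_tiff(tmp_path / "post.tif", role="post")
    assert np.array_equal(back.pixels, post.pixels)
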