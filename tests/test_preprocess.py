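"""Preprocessing chain: dark subtraction, response correction, rolling-ball
baseline, SNV normalization."""

import numpy as np
import pytest

from ramanqf.preprocess import (
    RollingBallConfig,
    ZeroVarianceError,
    correct_response,
    preprocess_pipeline,
    rolling_ball_decompose,
    snv_normalize,
    subtract_dark,
)
from ramanqf.spectra import (
    AcquisitionParams,
    RawSpectrum,
    ResponseCurve,
    SpectrumValidationError,
    default_axis,
)


class TestSubtractDark:
    def test_identical_dark_cancels_exactly(self, axis, params, rng):
        s = RawSpectrum(axis, rng.uniform(10, 100, len(axis)), params)
        out = subtract_dark(s, s)
        assert np.array_equal(out.counts, np.zeros(len(axis)))

    def test_zero_dark_is_identity(self, axis, params, rng):
        s = RawSpectrum(axis, rng.uniform(10, 100, len(axis)), params)
        dark = RawSpectrum(axis, np.zeros(len(axis)), params)
        assert np.array_equal(subtract_dark(s, dark).counts, s.counts)

    def test_constant_offset_recovered(self, axis, params, rng):
        dark_counts = rng.uniform(10, 50, len(axis))
        dark = RawSpectrum(axis, dark_counts, params)
        s = RawSpectrum(axis, dark_counts + 100.0, params)
        assert np.allclose(subtract_dark(s, dark).counts, 100.0)

    def test_dark_scaled_by_exposure_product(self, axis):
        # dark acquired at n*t = 1000 ms, measurement at n*t = 250 ms:
        # a quarter of the dark counts must be removed
        dark = RawSpectrum(axis, np.full(len(axis), 400.0), AcquisitionParams(10, 100.0, 1.0))
        s = RawSpectrum(axis, np.full(len(axis), 150.0), AcquisitionParams(5, 50.0, 30.0))
        assert np.allclose(subtract_dark(s, dark).counts, 50.0)

    def test_result_clipped_at_zero(self, axis, params):
        dark = RawSpectrum(axis, np.full(len(axis), 100.0), params)
        s = RawSpectrum(axis, np.full(len(axis), 30.0), params)
        assert np.array_equal(subtract_dark(s, dark).counts, np.zeros(len(axis)))


class TestCorrectResponse:
    def test_unit_gain_is_identity(self, axis, params, rng):
        s = RawSpectrum(axis, rng.uniform(0, 10, len(axis)), params)
        rc = ResponseCurve(axis, np.ones(len(axis)))
        assert np.array_equal(correct_response(s, rc).counts, s.counts)

    def test_gain_two_halves_counts(self, axis, params):
        s = RawSpectrum(axis, np.full(len(axis), 10.0), params)
        rc = ResponseCurve(axis, np.full(len(axis), 2.0))
        assert np.allclose(correct_response(s, rc).counts, 5.0)

    def test_inverse_gain_roundtrip(self, axis, params, rng, response):
        s = RawSpectrum(axis, rng.uniform(1, 10, len(axis)), params)
        back = correct_response(correct_response(s, response), response.inverse())
        assert np.allclose(back.counts, s.counts)


class TestRollingBall:
    def test_flat_spectrum_gives_zero_raman_exactly(self, axis, params):
        s = RawSpectrum(axis, np.full(len(axis), 5000.0), params)
        d = rolling_ball_decompose(s)
        assert np.array_equal(d.raman, np.zeros(len(axis)))
        assert np.allclose(d.background, 5000.0)

    def test_narrow_gaussian_peak_area_recovered(self, axis, params):
        # sigma = 4 cm^-1 peak (amplitude 1000) on a flat 5000 background:
        # recovered area within 10% of the analytic 1000 * sigma * sqrt(2 pi)
        x = axis.values
        peak = 1000.0 * np.exp(-0.5 * ((x - 1100.0) / 4.0) ** 2)
        s = RawSpectrum(axis, 5000.0 + peak, params)
        d = rolling_ball_decompose(s, RollingBallConfig(radius_cm1=50.0))
        area = np.trapezoid(d.raman, x)
        true_area = 1000.0 * 4.0 * np.sqrt(2 * np.pi)
        assert area == pytest.approx(true_area, rel=0.10)

    def test_smooth_broad_background_leaves_no_raman(self, axis, params):
        x = axis.values
        bg = 3e4 * np.exp(-0.5 * ((x - 1000.0) / 400.0) ** 2)
        d = rolling_ball_decompose(RawSpectrum(axis, bg, params))
        assert np.max(np.abs(d.raman)) < 0.01 * bg.max()

    def test_decomposition_reconstructs_input(self, noise_free_spectrum):
        d = rolling_ball_decompose(noise_free_spectrum)
        assert np.allclose(d.raman + d.background, noise_free_spectrum.counts)

    def test_background_never_exceeds_signal(self, axis, params, rng):
        # opening property holds even on pure-noise input
        counts = rng.poisson(3000.0, len(axis)).astype(float)
        d = rolling_ball_decompose(RawSpectrum(axis, counts, params))
        assert np.all(d.background <= counts + 1e-9)
        assert np.all(d.raman >= 0)

    def test_degenerate_radius_rejected(self, axis, params):
        s = RawSpectrum(axis, np.ones(len(axis)), params)
        with pytest.raises(SpectrumValidationError, match="degenerate"):
            rolling_ball_decompose(s, RollingBallConfig(radius_cm1=1.0))


class TestSnv:
    def test_closed_form_three_points(self, ):
        axis3 = default_axis(400, 402, 3)
        out = snv_normalize(np.array([1.0, 2.0, 3.0]), axis3)
        assert np.allclose(out.intensity, [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_idempotent(self, axis, rng):
        x = rng.normal(0, 3, len(axis))
        once = snv_normalize(x, axis).intensity
        twice = snv_normalize(once, axis).intensity
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_input_rejected(self, axis):
        with pytest.raises(ZeroVarianceError):
            snv_normalize(np.full(len(axis), 3.0), axis)

    def test_contract_mean_zero_std_one(self, axis, rng):
        # inputs spanning several orders of magnitude still meet the 1e-9 contract
        x = rng.lognormal(0, 4, len(axis))
        out = snv_normalize(x, axis)
        assert abs(out.intensity.mean()) < 1e-9
        assert abs(out.intensity.std() - 1.0) < 1e-9


class TestPipeline:
    def test_background_recovered_from_simulated_truth(
        self, axis, profile, params, dark, response, detector
    ):
        # noise-free rendering through gain + dark, then the full chain:
        # recovered background within 5% RMSE (relative to its maximum)
        dose = params.dose
        truth_bg = dose * profile.background_rate
        counts = (dose * (profile.raman_rate + profile.background_rate) * response.gain
                  + params.exposure_product_ms * detector.dark_rate)
        s = RawSpectrum(axis, counts, params)
        decomposed, processed = preprocess_pipeline(s, dark, response, None)
        rmse = np.sqrt(np.mean((decomposed.background - truth_bg) ** 2))
        assert rmse / truth_bg.max() < 0.05
        assert abs(processed.intensity.mean()) < 1e-9

    def test_zero_raman_rates_flagged_as_degenerate(self, axis, params, dark, response):
        # a spectrum with no Raman signal and flat background yields a
        # constant residual, which SNV must reject rather than normalize
        counts = np.full(len(axis), 4000.0)
        with pytest.raises(ZeroVarianceError):
            preprocess_pipeline(RawSpectrum(axis, counts, params),
                                RawSpectrum(axis, np.zeros(len(axis)), params),
                                ResponseCurve(axis, np.ones(len(axis))), None)

    def test_deterministic(self, noise_free_spectrum, dark, response):
        d1, p1 = preprocess_pipeline(noise_free_spectrum, dark, response, None)
        d2, p2 = preprocess_pipeline(noise_free_spectrum, dark, response, None)
        assert np.array_equal(d1.raman, d2.raman)
        assert np.array_equal(p1.intensity, p2.intensity)
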