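"""Synthetic-data generator: tissue profiles, detector model, surrogate
reviewers, full datasets."""

import numpy as np
import pytest

from ramanqf.quality import QfConfig, compute_qf
from ramanqf.preprocess import rolling_ball_decompose
from ramanqf.simulate import (
    CLASS_MULTIPLIERS,
    HIGH_QUALITY_SNR,
    DetectorModel,
    SimConfig,
    generate_dataset,
    make_tissue_profile,
    sample_measurement,
    surrogate_qs,
)
from ramanqf.spectra import AcquisitionParams, SpectrumValidationError


class TestTissueProfile:
    def test_same_seed_reproduces_profile(self, axis):
        p1 = make_tissue_profile("cancer", seed=42, axis=axis)
        p2 = make_tissue_profile("cancer", seed=42, axis=axis)
        assert np.array_equal(p1.raman_rate, p2.raman_rate)
        assert np.array_equal(p1.background_rate, p2.background_rate)

    def test_unknown_class_rejected(self):
        with pytest.raises(SpectrumValidationError):
            make_tissue_profile("polyp", seed=0)

    def test_background_dominates_raman(self, profile):
        # fingerprint-region tissue measurements are background-dominated
        assert profile.raman_fraction < 0.05

    def test_null_tissue_yields_zero_qf(self, axis, params, detector):
        profile = make_tissue_profile("normal", seed=1, axis=axis, peaks=())
        assert np.all(profile.raman_rate == 0)
        # ground-truth decomposition: QF is exactly zero
        _, truth = sample_measurement(profile, detector, params, seed=0)
        assert compute_qf(truth, QfConfig(mode="all_four")) == 0.0
        # measured QF is limited to the small baseline-curvature residue,
        # far below the QF the same background carries with peaks present
        from ramanqf.spectra import RawSpectrum
        counts = params.dose * (profile.raman_rate + profile.background_rate)
        d = rolling_ball_decompose(RawSpectrum(axis, counts, params))
        with_peaks = make_tissue_profile("normal", seed=1, axis=axis)
        counts_p = params.dose * (with_peaks.raman_rate + with_peaks.background_rate)
        d_p = rolling_ball_decompose(RawSpectrum(axis, counts_p, params))
        assert compute_qf(d, QfConfig(mode="all_four")) < \
            0.2 * compute_qf(d_p, QfConfig(mode="all_four"))

    def test_class_band_ratio_shift_matches_multipliers(self, axis):
        # integrate the 1441 and 1082 windows of the noise-free rates: the
        # cancer/normal ratio-of-ratios equals the configured multiplier ratio
        normal = make_tissue_profile("normal", seed=0, axis=axis, peak_jitter_sd=0.0,
                                     background_jitter_sd=0.0)
        cancer = make_tissue_profile("cancer", seed=0, axis=axis, peak_jitter_sd=0.0,
                                     background_jitter_sd=0.0)

        def band_area(profile, center):
            m = np.abs(axis.values - center) <= 10.0
            return np.trapezoid(profile.raman_rate[m], axis.values[m])

        ratio_normal = band_area(normal, 1441.0) / band_area(normal, 1082.0)
        ratio_cancer = band_area(cancer, 1441.0) / band_area(cancer, 1082.0)
        mult = CLASS_MULTIPLIERS["cancer"]
        expected = mult[1441.0] / mult[1082.0]
        # windows overlap neighbouring lines, so allow a few percent
        assert ratio_cancer / ratio_normal == pytest.approx(expected, rel=0.05)


class TestSampleMeasurement:
    def test_zero_rates_and_dark_give_zero_counts(self, axis, params):
        profile = make_tissue_profile("normal", seed=1, axis=axis, peaks=())
        null = profile.__class__(axis, np.zeros(len(axis)), np.zeros(len(axis)), "normal")
        det = DetectorModel(dark_rate=0.0, read_noise_sd=0.0)
        raw, truth = sample_measurement(null, det, params, seed=0)
        assert np.array_equal(raw.counts, np.zeros(len(axis)))
        assert np.array_equal(truth.raman, np.zeros(len(axis)))

    def test_mean_and_variance_follow_poisson_statistics(self, rng):
        # small axis, many replicates: per-bin sample mean within 3 standard
        # errors of expectation and index of dispersion within [0.9, 1.1]
        from ramanqf.spectra import WavenumberAxis
        from ramanqf.simulate import TissueProfile

        axis = WavenumberAxis(np.linspace(1400, 1500, 8))
        r = np.full(8, 0.05)
        a = np.linspace(2.0, 6.0, 8)
        profile = TissueProfile(axis, r, a, "normal")
        det = DetectorModel(read_noise_sd=0.0)
        params = AcquisitionParams(5, 75.0, 30.0)
        n_rep = 10_000
        counts = np.empty((n_rep, 8))
        for i in range(n_rep):
            raw, _ = sample_measurement(profile, det, params, seed=rng)
            counts[i] = raw.counts
        expected = params.n_repeats * (
            params.exposure_time_ms * params.laser_power_mw * (r + a)
            + params.exposure_time_ms * det.dark_rate
        )
        se = np.sqrt(expected / n_rep)
        assert np.all(np.abs(counts.mean(axis=0) - expected) < 3.5 * se)
        dispersion = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        assert np.all((dispersion > 0.9) & (dispersion < 1.1))

    def test_ground_truth_carries_noise_free_dose(self, profile, detector, params):
        _, truth = sample_measurement(profile, detector, params, seed=1)
        assert np.allclose(truth.raman, params.dose * profile.raman_rate)
        assert np.allclose(truth.background, params.dose * profile.background_rate)

    def test_saturation_flagged_and_clipped(self, axis, profile):
        det = DetectorModel(full_well=100.0)
        params = AcquisitionParams(2, 75.0, 60.0)
        raw, _ = sample_measurement(profile, det, params, seed=3)
        assert raw.meta["saturated"] is True
        assert raw.counts.max() <= params.n_repeats * det.full_well


class TestSurrogateReviewers:
    def test_zero_snr_floors_the_scale(self):
        assert surrogate_qs([0.0], reviewer_noise_sd=0.0, seed=0) == 3

    def test_saturating_snr_ceils_the_scale(self):
        assert surrogate_qs([1e6], reviewer_noise_sd=0.0, seed=0) == 9

    def test_high_quality_regime_scores_high(self, rng):
        draws = np.array([surrogate_qs([HIGH_QUALITY_SNR], seed=rng) for _ in range(1000)])
        assert np.mean(draws >= 7) >= 0.8

    def test_borderline_snr_straddles_the_6_7_boundary(self, rng):
        # at the reviewer midpoint the score distribution spans both labels,
        # producing the borderline 6/7 cases the qS scheme is known for
        from ramanqf.simulate import DEFAULT_SNR_HALF

        boundary = DEFAULT_SNR_HALF * np.sqrt(2.0)  # grade ~2.33: qS boundary
        draws = np.array([surrogate_qs([boundary], seed=rng) for _ in range(1000)])
        frac_high = np.mean(draws >= 7)
        assert 0.1 < frac_high < 0.9
        assert {6, 7} <= set(draws.tolist())


class TestGenerateDataset:
    def test_default_sizes_and_class_ratio(self, tmp_path):
        cfg = SimConfig(seed=123)
        manifest = generate_dataset(cfg, tmp_path / "ds")
        # 44 patients x ~7 points: within +-44 of 308 measurements
        assert 264 <= len(manifest) <= 352
        assert manifest.patient_id.nunique() == 44
        counts = manifest.pathology.value_counts()
        ratio = counts["normal"] / counts["cancer"]
        assert ratio == pytest.approx(1.75, rel=0.15)

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=7, n_patients=4)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.tsv").read_bytes() == \
               (tmp_path / "b" / "manifest.tsv").read_bytes()

    def test_minimal_dataset_flows_through_pipeline(self, tmp_path):
        from ramanqf.evaluate import process_dataset

        cfg = SimConfig(seed=5, n_patients=1, points_per_patient=1.0)
        manifest = generate_dataset(cfg, tmp_path / "tiny")
        assert len(manifest) >= 1
        ds = process_dataset(tmp_path / "tiny")
        assert len(ds) == len(manifest)
        assert np.all(ds.qf >= 0)

    def test_manifest_records_acquisition_ranges(self, tmp_path):
        cfg = SimConfig(seed=2, n_patients=8)
        manifest = generate_dataset(cfg, tmp_path / "ds")
        assert manifest.n.between(5, 10).all()
        assert set(manifest.t_ms.unique()) <= {50.0, 75.0}
        assert manifest.power_mW.between(10.0, 75.0).all()
        assert manifest.qs.between(3, 9).all()


class TestMonotoneQuality:
    def test_more_repeats_raise_qf_and_qs(self, axis, profile, detector, rng):
        # stochastic monotonicity: averaged over replicates, both the
        # measured QF and the surrogate qS increase with n
        from ramanqf.quality import band_mean_snr, raman_snr_from_rates

        qf_means, qs_means = [], []
        for n in (2, 8):
            params = AcquisitionParams(n, 75.0, 30.0)
            qfs, qss = [], []
            for _ in range(30):
                raw, _ = sample_measurement(profile, detector, params, seed=rng)
                d = rolling_ball_decompose(raw.with_counts(raw.counts))
                qfs.append(compute_qf(d))
                snr = raman_snr_from_rates(profile.raman_rate, profile.background_rate, params)
                qss.append(surrogate_qs(band_mean_snr(snr, axis, names=["1441", "1659"]),
                                        seed=rng))
            qf_means.append(np.mean(qfs))
            qs_means.append(np.mean(qss))
        assert qf_means[1] > qf_means[0]
        assert qs_means[1] > qs_means[0]
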