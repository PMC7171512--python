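"""Synthetic intraoperative brain Raman measurements.

The generator emulates the regime of fingerprint-region (~400-1800 cm^-1)
in-vivo brain measurements: a smooth fluorescence-dominated background one
to two orders of magnitude above narrow Raman peaks at canonical brain
bands, Poisson shot noise scaling with the accumulated dose n*t*I_S,
additive dark counts, small Gaussian read noise, and two tissue classes
(normal / cancer) differing subtly in band-intensity ratios — cancer
tissue has weaker lipid bands (1441, 1659 cm^-1) and stronger nucleic-acid
bands (1082, 1087 cm^-1).

Raman peaks are Lorentzian (the natural line shape); the background is a
broad two-component Gaussian mixture with log-normal patient-to-patient
amplitude variation.  Rates are photoelectrons per (ms * mW), so expected
detector counts per bin are ``n * t * I_S * (r + a) * gain + n * t *
dark_rate``.

Surrogate reviewers replace the visual quality scoring: three independent
graders each map the true mean in-band SNR through a saturating monotone
curve to a 1-3 grade with Gaussian grading noise; their sum is the quality
score qS in [3, 9], with qS >= 7 meaning "high quality".
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import write_manifest, write_response, write_spectrum
from .quality import band_mean_snr, raman_snr_from_rates
from .spectra import (
    AcquisitionParams,
    BandSet,
    DecomposedSpectrum,
    RawSpectrum,
    ResponseCurve,
    SpectrumValidationError,
    WavenumberAxis,
    default_axis,
)

__all__ = [
    "LorentzianPeak",
    "TissueProfile",
    "DetectorModel",
    "SimConfig",
    "DEFAULT_PEAKS",
    "CLASS_MULTIPLIERS",
    "make_tissue_profile",
    "sample_measurement",
    "surrogate_qs",
    "generate_dataset",
    "make_response_curve",
    "make_dark_reference",
]


@dataclass(frozen=True)
class LorentzianPeak:
    """A Raman line: center (cm^-1), amplitude (rate at center), HWHM gamma."""

    center: float
    amplitude: float
    gamma: float

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * self.gamma**2 / (self.gamma**2 + (x - self.center) ** 2)


# Canonical brain-tissue bands: phenylalanine 1004, nucleic acids 1082/1087,
# amide III 1300, tryptophan 1339, CH2/CH3 deformation 1441, amide II 1553,
# amide I 1659.  Amplitudes are photoelectron rates per (ms*mW) at the line
# center, chosen so Raman peaks sit at a few percent of the background.
DEFAULT_PEAKS: tuple[LorentzianPeak, ...] = (
    LorentzianPeak(1004.0, 0.12, 5.0),
    LorentzianPeak(1082.0, 0.10, 9.0),
    LorentzianPeak(1087.0, 0.08, 9.0),
    LorentzianPeak(1300.0, 0.12, 10.0),
    LorentzianPeak(1339.0, 0.10, 10.0),
    LorentzianPeak(1441.0, 0.18, 12.0),
    LorentzianPeak(1553.0, 0.07, 10.0),
    LorentzianPeak(1659.0, 0.16, 13.0),
)

#: Class-dependent amplitude multipliers by band center: cancer loses lipid
#: signal (CH2/CH3 1441, and amide I 1659 less so since proteins mix in),
#: gains nucleic-acid signal (1082/1087), phenylalanine (1004) and
#: tryptophan (1339), and loses amide III (1300); infiltrated tissue sits
#: halfway.  The 1441/1082 band-intensity ratio shifts by ~16% between the
#: classes — subtle enough that classification is quality-sensitive.
CLASS_MULTIPLIERS: dict[str, dict[float, float]] = {
    "normal": {},
    "cancer": {1004.0: 1.20, 1082.0: 1.14, 1087.0: 1.14, 1300.0: 0.84,
               1339.0: 1.16, 1441.0: 0.94, 1659.0: 0.97},
    "infiltrated": {1004.0: 1.10, 1082.0: 1.07, 1087.0: 1.07, 1300.0: 0.92,
                    1339.0: 1.08, 1441.0: 0.97, 1659.0: 0.985},
}

# Broad fluorescence background: (center cm^-1, sigma cm^-1, amplitude rate)
_BACKGROUND_COMPONENTS = ((900.0, 450.0, 5.0), (1500.0, 380.0, 2.8))
_BACKGROUND_OFFSET = 0.5


@dataclass(frozen=True, eq=False)
class TissueProfile:
    """Simulator ground truth: per-bin Raman and background photon rates."""

    axis: WavenumberAxis
    raman_rate: np.ndarray
    background_rate: np.ndarray
    class_label: str

    def __post_init__(self) -> None:
        r = np.asarray(self.raman_rate, dtype=float)
        a = np.asarray(self.background_rate, dtype=float)
        if r.size != len(self.axis) or a.size != len(self.axis):
            raise SpectrumValidationError("rate arrays must match axis length")
        if np.any(r < 0) or np.any(a < 0):
            raise SpectrumValidationError("rates must be non-negative")
        object.__setattr__(self, "raman_rate", r)
        object.__setattr__(self, "background_rate", a)

    @property
    def raman_fraction(self) -> float:
        """Integrated Raman / total signal fraction (background dominance check)."""
        total = float(self.raman_rate.sum() + self.background_rate.sum())
        return float(self.raman_rate.sum()) / total if total > 0 else 0.0


@dataclass(frozen=True)
class DetectorModel:
    """CCD detector: dark rate, read noise, and full-well depth per readout."""

    dark_rate: float = 0.02          # counts / ms / bin
    read_noise_sd: float = 2.0       # counts / bin / readout (negligible vs shot noise)
    full_well: float = 65535.0       # counts / bin / readout (16-bit CCD)

    def __post_init__(self) -> None:
        if self.dark_rate < 0 or self.read_noise_sd < 0 or self.full_well <= 0:
            raise SpectrumValidationError("detector parameters must be non-negative, full_well > 0")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def make_tissue_profile(
    class_label: str,
    seed: int | np.random.Generator | None = None,
    axis: WavenumberAxis | None = None,
    peaks: tuple[LorentzianPeak, ...] = DEFAULT_PEAKS,
    background_scale: float = 1.0,
    peak_jitter_sd: float = 0.02,
    background_jitter_sd: float = 0.3,
    background_shape_jitter_sd: float = 0.0,
    background_center_jitter_cm1: float = 0.0,
) -> TissueProfile:
    """Draw a tissue profile for one class.

    ``background_jitter_sd`` is the sigma of the log-normal factor applied
    to the whole background amplitude (patient-to-patient fluorescence
    spread); ``peak_jitter_sd`` the per-peak log-normal amplitude jitter.
    The background mixture's component weights and centers also vary
    (``background_shape_jitter_sd``, ``background_center_jitter_cm1``):
    tissue autofluorescence differs in shape, not just brightness, from
    site to site.
    """
    if class_label not in CLASS_MULTIPLIERS:
        raise SpectrumValidationError(
            f"unknown tissue class {class_label!r}; choose from {list(CLASS_MULTIPLIERS)}"
        )
    rng = _rng(seed)
    axis = axis or default_axis()
    x = axis.values
    mult = CLASS_MULTIPLIERS[class_label]
    raman = np.zeros_like(x)
    for peak in peaks:
        amp = peak.amplitude * mult.get(peak.center, 1.0)
        if peak_jitter_sd > 0:
            amp *= float(np.exp(rng.normal(0.0, peak_jitter_sd)))
        raman += LorentzianPeak(peak.center, amp, peak.gamma).evaluate(x)
    bg_factor = background_scale
    if background_jitter_sd > 0:
        bg_factor *= float(np.exp(rng.normal(0.0, background_jitter_sd)))
    background = np.full_like(x, _BACKGROUND_OFFSET)
    for center, sigma, amp in _BACKGROUND_COMPONENTS:
        if background_shape_jitter_sd > 0:
            amp = amp * float(np.exp(rng.normal(0.0, background_shape_jitter_sd)))
        if background_center_jitter_cm1 > 0:
            center = center + float(rng.normal(0.0, background_center_jitter_cm1))
        background += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    background *= bg_factor
    return TissueProfile(axis, raman, background, class_label)


def sample_measurement(
    profile: TissueProfile,
    det: DetectorModel,
    params: AcquisitionParams,
    seed: int | np.random.Generator | None = None,
    response: ResponseCurve | None = None,
    meta: Mapping[str, object] | None = None,
) -> tuple[RawSpectrum, DecomposedSpectrum]:
    """Sample one measurement (counts summed over the n repeats).

    Expected counts per bin are ``n t I_S (r + a) gain + n t dark_rate``;
    observed counts are Poisson with Gaussian read noise of sd
    ``read_noise_sd * sqrt(n)`` added, clipped at zero.  Saturation of a
    single readout (expected per-readout counts above the full well) is
    flagged in ``meta['saturated']``, never silent.

    Returns the raw spectrum and the noise-free ground-truth decomposition
    (``n t I_S r`` and ``n t I_S a``, before response gain and dark).
    """
    rng = _rng(seed)
    n, t, power = params.n_repeats, params.exposure_time_ms, params.laser_power_mw
    gain = np.ones(len(profile.axis)) if response is None else response.gain
    if response is not None and not response.axis.equals(profile.axis):
        raise SpectrumValidationError("response curve must share the profile axis")
    per_readout = t * power * (profile.raman_rate + profile.background_rate) * gain + t * det.dark_rate
    saturated = bool(np.any(per_readout > det.full_well))
    # a saturated bin clips at the full well on every readout
    expected = n * np.minimum(per_readout, det.full_well)
    counts = rng.poisson(expected).astype(float)
    if det.read_noise_sd > 0:
        counts += rng.normal(0.0, det.read_noise_sd * np.sqrt(n), size=counts.size)
    counts = np.clip(counts, 0.0, n * det.full_well)
    all_meta = dict(meta or {})
    all_meta["saturated"] = saturated
    raw = RawSpectrum(profile.axis, counts, params, all_meta)
    dose = params.dose
    truth = DecomposedSpectrum(
        profile.axis, dose * profile.raman_rate, dose * profile.background_rate, params
    )
    return raw, truth


# --- surrogate visual quality scoring --------------------------------------

#: Mean in-band SNR at which a noise-free reviewer grade reaches 2 (midpoint
#: of the 1-3 scale); the saturating logistic map is
#: grade = 1 + 2 s^2 / (s^2 + SNR_HALF^2).
DEFAULT_SNR_HALF = 4.5
DEFAULT_REVIEWER_NOISE_SD = 0.15
#: Mean in-band SNR defining the "clearly high quality" regime: calibrated
#: so spectra at or above it receive qS >= 7 with probability >= 0.8.
HIGH_QUALITY_SNR = 12.0


def surrogate_qs(
    true_band_snr: np.ndarray,
    reviewer_noise_sd: float = DEFAULT_REVIEWER_NOISE_SD,
    seed: int | np.random.Generator | None = None,
    snr_half: float = DEFAULT_SNR_HALF,
    n_reviewers: int = 3,
) -> int:
    """Quality score qS from three noisy surrogate reviewers.

    Each reviewer grade is
    ``clip(round(1 + 2 s^2 / (s^2 + snr_half^2) + eps), 1, 3)`` with ``s``
    the mean of the per-band SNR values and ``eps`` Gaussian grading
    noise; qS is the sum of the grades.  The quadratic logistic keeps
    clearly poor spectra at grade 1 and saturates clearly good ones at 3,
    leaving a genuine ambiguous zone around ``snr_half``.
    """
    s = float(np.mean(np.asarray(true_band_snr, dtype=float)))
    if s < 0:
        raise SpectrumValidationError("band SNR values must be >= 0")
    rng = _rng(seed)
    base = 1.0 + 2.0 * s**2 / (s**2 + snr_half**2)
    grades = np.clip(np.round(base + rng.normal(0.0, reviewer_noise_sd, size=n_reviewers)), 1, 3)
    return int(grades.sum())


# --- full dataset -----------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for a simulated intraoperative dataset.

    Defaults mirror the acquisition regime of a hand-held probe brain
    study: 44 patients, on average 7 acquisition points each, n = 5-10
    co-located repeats per point, exposure 50 or 75 ms, laser power 10-75
    mW at the sample, cancer:normal ratio ~1:1.75.
    """

    seed: int = 0
    n_patients: int = 44
    points_per_patient: float = 7.0        # Poisson mean, min 1 point
    n_repeats_range: tuple[int, int] = (5, 10)
    exposure_choices_ms: tuple[float, ...] = (50.0, 75.0)
    # laser power at sample spans 10-75 mW; drawn from a low-power regime
    # (conservative settings near eloquent or bleeding-prone sites) or a
    # high-power regime, each equally likely
    power_ranges_mw: tuple[tuple[float, float], ...] = ((10.0, 18.0), (55.0, 75.0))
    cancer_fraction: float = 1.0 / 2.75    # cancer:normal = 1:1.75
    infiltrated_fraction: float = 0.0
    reviewer_noise_sd: float = DEFAULT_REVIEWER_NOISE_SD
    snr_half: float = DEFAULT_SNR_HALF
    band_set: BandSet = field(default_factory=BandSet.default)
    qs_band_names: tuple[str, ...] = ("1441", "1659")
    patient_background_sd: float = 0.25   # log-normal sigma, patient level
    point_background_sd: float = 0.15     # log-normal sigma, point level
    peak_jitter_sd: float = 0.02
    detector: DetectorModel = field(default_factory=DetectorModel)
    axis_start: float = 400.0
    axis_stop: float = 1800.0
    n_bins: int = 1000

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.points_per_patient <= 0:
            raise SpectrumValidationError("need at least one patient and a positive point rate")
        if not (0 < self.cancer_fraction < 1) or self.infiltrated_fraction < 0:
            raise SpectrumValidationError("class fractions out of range")
        if self.cancer_fraction + self.infiltrated_fraction >= 1:
            raise SpectrumValidationError("class fractions must sum below 1")

    def make_axis(self) -> WavenumberAxis:
        return WavenumberAxis(np.linspace(self.axis_start, self.axis_stop, self.n_bins))


def make_response_curve(axis: WavenumberAxis) -> ResponseCurve:
    """Smooth synthetic intensity-response curve (gain ~0.85-1.15)."""
    x = axis.values
    gain = 1.0 + 0.15 * np.exp(-0.5 * ((x - 1200.0) / 600.0) ** 2) - 0.15 * (x - x[0]) / (x[-1] - x[0])
    return ResponseCurve(axis, gain)


def make_dark_reference(
    axis: WavenumberAxis,
    det: DetectorModel,
    seed: int | np.random.Generator | None = None,
    n_repeats: int = 200,
    exposure_time_ms: float = 75.0,
) -> RawSpectrum:
    """Laser-off dark reference, averaged over many readouts (low noise).

    The laser is off during a dark acquisition; the nominal 1 mW power in
    the stored parameters is a placeholder (only n*t matters for scaling).
    """
    rng = _rng(seed)
    expected = n_repeats * exposure_time_ms * det.dark_rate
    counts = rng.poisson(expected, size=len(axis)).astype(float)
    params = AcquisitionParams(n_repeats, exposure_time_ms, 1.0)
    return RawSpectrum(axis, counts, params, {"kind": "dark"})


def _derived_seed(base: int, *parts: int) -> int:
    blob = ("ramanqf:" + ":".join(str(p) for p in (base, *parts))).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "little") % (2**31)


def generate_dataset(cfg: SimConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write a full labeled dataset: spectra, dark, response curve, manifest.

    Each acquisition point yields one measurement (counts summed over its
    n repeats).  The manifest records measurement_id, path, acquisition
    parameters, patient, pathology, surrogate qS, the true mean in-band
    SNR and a saturation flag.  Everything is a pure function of the
    config (including its seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    axis = cfg.make_axis()
    det = cfg.detector
    response = make_response_curve(axis)
    dark = make_dark_reference(axis, det, seed=_derived_seed(cfg.seed, 0xDA))
    write_response(response, out_dir / "response.tsv")
    write_spectrum(dark, out_dir / "dark.tsv")

    rows = []
    rng = np.random.default_rng(_derived_seed(cfg.seed, 0x5717))
    for p in range(cfg.n_patients):
        patient_id = f"P{p:03d}"
        n_points = max(1, int(rng.poisson(cfg.points_per_patient)))
        # log-normal patient-to-patient fluorescence spread, plus smaller
        # point-to-point jitter inside make_tissue_profile
        patient_bg_scale = float(np.exp(rng.normal(0.0, cfg.patient_background_sd)))
        for q in range(n_points):
            u = rng.uniform()
            if u < cfg.cancer_fraction:
                label = "cancer"
            elif u < cfg.cancer_fraction + cfg.infiltrated_fraction:
                label = "infiltrated"
            else:
                label = "normal"
            profile = make_tissue_profile(
                label, seed=rng, axis=axis, background_scale=patient_bg_scale,
                background_jitter_sd=cfg.point_background_sd,
                peak_jitter_sd=cfg.peak_jitter_sd,
            )
            power_lo, power_hi = cfg.power_ranges_mw[rng.integers(len(cfg.power_ranges_mw))]
            params = AcquisitionParams(
                int(rng.integers(cfg.n_repeats_range[0], cfg.n_repeats_range[1] + 1)),
                float(rng.choice(cfg.exposure_choices_ms)),
                float(rng.uniform(power_lo, power_hi)),
            )
            mid = f"{patient_id}_pt{q:02d}"
            raw, _truth = sample_measurement(
                profile, det, params, seed=rng, response=response,
                meta={"measurement_id": mid, "patient_id": patient_id, "pathology": label},
            )
            true_snr = raman_snr_from_rates(profile.raman_rate, profile.background_rate, params)
            band_snr = band_mean_snr(true_snr, axis, cfg.band_set, cfg.qs_band_names)
            if raw.meta["saturated"]:
                # reviewers see a clipped, peak-less spectrum and grade it
                # at the bottom of the scale regardless of the photon dose
                band_snr = np.zeros_like(band_snr)
            qs = surrogate_qs(band_snr, cfg.reviewer_noise_sd, seed=rng, snr_half=cfg.snr_half)
            fname = f"{mid}.tsv"
            write_spectrum(raw, out_dir / fname)
            rows.append({
                "measurement_id": mid,
                "path": fname,
                "n": params.n_repeats,
                "t_ms": params.exposure_time_ms,
                "power_mW": params.laser_power_mw,
                "qs": qs,
                "pathology": label,
                "patient_id": patient_id,
                "true_band_snr": float(np.mean(band_snr)),
                "saturated": bool(raw.meta["saturated"]),
            })
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.tsv")
    return manifest
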