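"""Shot-noise Raman SNR per spectral bin and the band-summed quality factor.

In a background-dominated tissue Raman measurement the per-bin noise is
shot noise on the *total* photon count.  With accumulated (over the n
repeats) Raman counts ``R_j`` and background counts ``A_j``, the SNR of
the Raman contribution in bin ``j`` is

    SNR_j = R_j / sqrt(R_j + A_j).

When ``r_j`` and ``a_j`` are photon *rates* per (ms * mW), accumulated
counts are ``R_j = n t I_S r_j``, and the same expression becomes

    SNR_j = sqrt(n t I_S) * r_j / sqrt(r_j + a_j),

which makes the sqrt(n)-, sqrt(t)- and sqrt(I_S)-scaling of spectral
quality explicit.  The quality factor sums SNR_j over every bin inside a
set of preselected tissue Raman bands (C-C stretch 1087, CH2/CH3
deformation 1441, amide II 1553, amide I 1659 cm^-1 by default):

    QF = sum_{j in bands} SNR_j.

A spectrum is labeled high quality when QF exceeds a calibrated threshold
(strictly: ``QF > threshold``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .spectra import (
    AcquisitionParams,
    BandSet,
    DecomposedSpectrum,
    QualityRecord,
    SpectrumValidationError,
    WavenumberAxis,
)

__all__ = [
    "QF_MODES",
    "DEFAULT_QF_THRESHOLD",
    "QfConfig",
    "raman_snr_per_bin",
    "raman_snr_from_rates",
    "compute_qf",
    "band_mean_snr",
    "apply_quality_threshold",
]

#: Band combinations the quality factor can be evaluated over.
QF_MODES: dict[str, tuple[str, ...]] = {
    "all_four": ("1087", "1441", "1553", "1659"),
    "b1441": ("1441",),
    "b1659": ("1659",),
    "b1441_plus_1659": ("1441", "1659"),
}

#: Default decision threshold; instrument- and binning-dependent, so it
#: must be recalibrated (see evaluate.roc_quality) for any new system.
DEFAULT_QF_THRESHOLD = 145.0


@dataclass(frozen=True)
class QfConfig:
    """Band selection and decision threshold for the quality factor."""

    band_set: BandSet = field(default_factory=BandSet.default)
    mode: str = "b1441_plus_1659"
    threshold: float = DEFAULT_QF_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in QF_MODES:
            raise SpectrumValidationError(f"unknown QF mode {self.mode!r}; choose from {list(QF_MODES)}")
        if self.threshold < 0:
            raise SpectrumValidationError("QF threshold must be >= 0")
        names = set(self.band_set.names)
        wanted = [n for n in QF_MODES[self.mode] if n in names]
        if not wanted:
            raise SpectrumValidationError(
                f"mode {self.mode!r} selects no band present in the band set {self.band_set.names}"
            )

    @property
    def selected_names(self) -> tuple[str, ...]:
        names = set(self.band_set.names)
        return tuple(n for n in QF_MODES[self.mode] if n in names)


def _snr(numer: np.ndarray, total: np.ndarray) -> np.ndarray:
    out = np.zeros_like(numer, dtype=float)
    nz = total > 0
    out[nz] = numer[nz] / np.sqrt(total[nz])
    return out


def raman_snr_per_bin(d: DecomposedSpectrum) -> np.ndarray:
    """Shot-noise SNR of the Raman contribution, per bin (counts domain).

    ``d.raman`` and ``d.background`` are totals accumulated over the n
    repeats; empty bins (R + A = 0) get SNR 0, the limit of the formula.
    """
    return _snr(d.raman, d.raman + d.background)


def raman_snr_from_rates(
    raman_rate: np.ndarray,
    background_rate: np.ndarray,
    params: AcquisitionParams,
) -> np.ndarray:
    """Rate-domain form: sqrt(n t I_S) * r / sqrt(r + a).

    ``raman_rate`` / ``background_rate`` are photon rates per (ms * mW);
    used for simulator ground truth and noise-free predictions.
    """
    r = np.asarray(raman_rate, dtype=float)
    a = np.asarray(background_rate, dtype=float)
    if np.any(r < 0) or np.any(a < 0):
        raise SpectrumValidationError("rates must be non-negative")
    return np.sqrt(params.dose) * _snr(r, r + a)


def compute_qf(d: DecomposedSpectrum, cfg: QfConfig | None = None) -> float:
    """Quality factor: per-bin Raman SNR summed over the selected bands."""
    cfg = cfg or QfConfig()
    mask = cfg.band_set.mask(d.axis, cfg.selected_names)
    if not mask.any():
        raise SpectrumValidationError(
            f"no axis bins fall inside the selected bands {cfg.selected_names}"
        )
    snr = raman_snr_per_bin(d)
    return float(np.sum(snr[mask]))


def band_mean_snr(
    snr: np.ndarray,
    axis: WavenumberAxis,
    band_set: BandSet | None = None,
    names: Sequence[str] | None = None,
) -> np.ndarray:
    """Mean per-bin SNR within each band, in band order."""
    band_set = band_set or BandSet.default()
    bands = band_set.bands if names is None else band_set.select(names).bands
    out = []
    for band in bands:
        m = band.mask(axis)
        out.append(float(np.mean(snr[m])) if m.any() else 0.0)
    return np.asarray(out)


def apply_quality_threshold(records: Iterable[QualityRecord], threshold: float) -> np.ndarray:
    """Binary labels: True (high quality) iff QF strictly exceeds the threshold."""
    return np.asarray([rec.qf > threshold for rec in records], dtype=bool)
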