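"""Core domain types for Raman spectra.

A spectrum lives on a :class:`WavenumberAxis` (Raman shifts in cm^-1,
ascending bin centers).  Raw detector counts are stored as totals
accumulated over the ``n`` repeat acquisitions of a measurement, together
with the acquisition parameters (number of repeats ``n``, exposure time
``t`` in ms, laser power at the sample ``I_S`` in mW) that the shot-noise
quality factor depends on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpectrumValidationError",
    "WavenumberAxis",
    "AcquisitionParams",
    "RawSpectrum",
    "ResponseCurve",
    "DecomposedSpectrum",
    "ProcessedSpectrum",
    "Band",
    "BandSet",
    "QualityRecord",
    "PATHOLOGY_LABELS",
    "default_axis",
    "resample_to_axis",
    "resample_response",
]

PATHOLOGY_LABELS = ("normal", "cancer", "infiltrated")


class SpectrumValidationError(ValueError):
    """Raised when a spectrum or axis violates its invariants."""


def _as_readonly_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SpectrumValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise SpectrumValidationError(f"{name} contains non-finite values")
    arr = arr.copy()
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True, eq=False)
class WavenumberAxis:
    """Strictly increasing Raman-shift bin centers in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_readonly_float(self.values, "axis values")
        if arr.size < 2:
            raise SpectrumValidationError("axis needs at least 2 bins")
        if not np.all(np.diff(arr) > 0):
            raise SpectrumValidationError("axis values must be strictly increasing")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Median bin spacing in cm^-1."""
        return float(np.median(np.diff(self.values)))

    @property
    def range(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def equals(self, other: "WavenumberAxis", atol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.values, other.values, atol=atol, rtol=0.0)
        )


def default_axis(start: float = 400.0, stop: float = 1800.0, n_bins: int = 1000) -> WavenumberAxis:
    """Fingerprint-region axis, ~1000 bins over 400-1800 cm^-1."""
    return WavenumberAxis(np.linspace(start, stop, n_bins))


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings entering the shot-noise SNR: n, t (ms), I_S (mW)."""

    n_repeats: int
    exposure_time_ms: float
    laser_power_mw: float

    def __post_init__(self) -> None:
        if int(self.n_repeats) != self.n_repeats or self.n_repeats < 1:
            raise SpectrumValidationError(f"n_repeats must be a positive integer, got {self.n_repeats}")
        object.__setattr__(self, "n_repeats", int(self.n_repeats))
        for name in ("exposure_time_ms", "laser_power_mw"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise SpectrumValidationError(f"{name} must be finite and > 0, got {v}")
            object.__setattr__(self, name, v)

    @property
    def exposure_product_ms(self) -> float:
        """n * t in ms — the factor dark counts accumulate with."""
        return self.n_repeats * self.exposure_time_ms

    @property
    def dose(self) -> float:
        """n * t * I_S in ms*mW — the shot-noise scale factor of Eq.-style SNR."""
        return self.n_repeats * self.exposure_time_ms * self.laser_power_mw


def _check_lengths(axis: WavenumberAxis, arr: np.ndarray, name: str) -> None:
    if arr.size != len(axis):
        raise SpectrumValidationError(
            f"{name} length {arr.size} does not match axis length {len(axis)}"
        )


@dataclass(frozen=True, eq=False)
class RawSpectrum:
    """Detector counts per bin, summed over the n repeats of a measurement."""

    axis: WavenumberAxis
    counts: np.ndarray
    params: AcquisitionParams
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = _as_readonly_float(self.counts, "counts")
        _check_lengths(self.axis, counts, "counts")
        if np.any(counts < 0):
            raise SpectrumValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "meta", dict(self.meta))

    def with_counts(self, counts, **meta_updates) -> "RawSpectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return RawSpectrum(self.axis, counts, self.params, meta)


@dataclass(frozen=True, eq=False)
class ResponseCurve:
    """Relative instrument intensity response (unitless gain per bin)."""

    axis: WavenumberAxis
    gain: np.ndarray

    def __post_init__(self) -> None:
        gain = _as_readonly_float(self.gain, "gain")
        _check_lengths(self.axis, gain, "gain")
        if np.any(gain <= 0):
            raise SpectrumValidationError("response gain must be > 0 everywhere")
        object.__setattr__(self, "gain", gain)

    def inverse(self) -> "ResponseCurve":
        return ResponseCurve(self.axis, 1.0 / self.gain)


@dataclass(frozen=True, eq=False)
class DecomposedSpectrum:
    """Per-bin Raman contribution r_j and smooth background a_j (counts).

    Both arrays are totals accumulated over the ``n`` repeats, after dark
    subtraction and intensity-response correction; the quality factor is
    computed from this decomposition.
    """

    axis: WavenumberAxis
    raman: np.ndarray
    background: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        raman = _as_readonly_float(self.raman, "raman")
        background = _as_readonly_float(self.background, "background")
        _check_lengths(self.axis, raman, "raman")
        _check_lengths(self.axis, background, "background")
        if np.any(raman < 0):
            raise SpectrumValidationError("raman contribution must be non-negative")
        if np.any(background < 0):
            raise SpectrumValidationError("background must be non-negative")
        object.__setattr__(self, "raman", raman)
        object.__setattr__(self, "background", background)

    @property
    def total(self) -> np.ndarray:
        return self.raman + self.background


@dataclass(frozen=True, eq=False)
class ProcessedSpectrum:
    """SNV-normalized Raman signal: zero mean, unit population std."""

    axis: WavenumberAxis
    intensity: np.ndarray

    _TOL = 1e-9

    def __post_init__(self) -> None:
        intensity = _as_readonly_float(self.intensity, "intensity")
        _check_lengths(self.axis, intensity, "intensity")
        if abs(float(intensity.mean())) > self._TOL:
            raise SpectrumValidationError("SNV intensity must have zero mean")
        if abs(float(intensity.std()) - 1.0) > self._TOL:
            raise SpectrumValidationError("SNV intensity must have unit population std")
        object.__setattr__(self, "intensity", intensity)


@dataclass(frozen=True)
class Band:
    """A named wavenumber window, center +/- half_width in cm^-1."""

    name: str
    center: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise SpectrumValidationError("band half_width must be > 0")

    def mask(self, axis: WavenumberAxis) -> np.ndarray:
        lo, hi = self.center - self.half_width, self.center + self.half_width
        return (axis.values >= lo) & (axis.values <= hi)


# Prominent brain-tissue bands used for quality assessment: C-C stretch
# (lipids/DNA), CH2/CH3 deformation (lipids/proteins), vC=C amide II
# (proteins), amide I (lipids/proteins/DNA).
DEFAULT_QF_BAND_CENTERS = (1087.0, 1441.0, 1553.0, 1659.0)
DEFAULT_BAND_HALF_WIDTH = 15.0


@dataclass(frozen=True)
class BandSet:
    """Named wavenumber windows over which the quality factor sums."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise SpectrumValidationError("BandSet needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise SpectrumValidationError("band names must be unique")

    @classmethod
    def default(cls, half_width: float = DEFAULT_BAND_HALF_WIDTH) -> "BandSet":
        return cls(tuple(Band(str(int(c)), c, half_width) for c in DEFAULT_QF_BAND_CENTERS))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def select(self, names: Iterable[str]) -> "BandSet":
        wanted = list(names)
        by_name = {b.name: b for b in self.bands}
        missing = [n for n in wanted if n not in by_name]
        if missing:
            raise KeyError(f"unknown band name(s): {missing}; have {list(by_name)}")
        return BandSet(tuple(by_name[n] for n in wanted))

    def mask(self, axis: WavenumberAxis, names: Sequence[str] | None = None) -> np.ndarray:
        """Boolean mask of axis bins falling inside any selected window."""
        bands = self.bands if names is None else self.select(names).bands
        mask = np.zeros(len(axis), dtype=bool)
        for band in bands:
            if not (axis.values[0] <= band.center <= axis.values[-1]):
                raise SpectrumValidationError(
                    f"band {band.name} center {band.center} cm^-1 outside axis range {axis.range}"
                )
            mask |= band.mask(axis)
        return mask


@dataclass(frozen=True)
class QualityRecord:
    """Per-measurement quality factor with optional qS score and pathology."""

    measurement_id: str
    qf: float
    qs: int | None = None
    pathology: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.qf) or self.qf < 0:
            raise SpectrumValidationError(f"qf must be finite and >= 0, got {self.qf}")
        if self.qs is not None:
            if int(self.qs) != self.qs or not (3 <= self.qs <= 9):
                raise SpectrumValidationError(
                    f"qS is the sum of three 1-3 reviewer grades, must be in [3, 9]; got {self.qs}"
                )
            object.__setattr__(self, "qs", int(self.qs))
        if self.pathology is not None and self.pathology not in PATHOLOGY_LABELS:
            raise SpectrumValidationError(
                f"pathology must be one of {PATHOLOGY_LABELS}, got {self.pathology!r}"
            )


def _interp_counts(src_axis: WavenumberAxis, values: np.ndarray, axis: WavenumberAxis) -> np.ndarray:
    lo, hi = src_axis.range
    tlo, thi = axis.range
    if tlo < lo - 1e-12 or thi > hi + 1e-12:
        raise SpectrumValidationError(
            f"target axis [{tlo}, {thi}] requires extrapolation beyond source [{lo}, {hi}]"
        )
    return np.interp(axis.values, src_axis.values, values)


def resample_to_axis(s: RawSpectrum, axis: WavenumberAxis) -> RawSpectrum:
    """Linearly interpolate a spectrum onto a target axis (no extrapolation)."""
    if s.axis.equals(axis):
        return RawSpectrum(axis, s.counts, s.params, s.meta)
    return RawSpectrum(axis, _interp_counts(s.axis, s.counts, axis), s.params, s.meta)


def resample_response(rc: ResponseCurve, axis: WavenumberAxis) -> ResponseCurve:
    if rc.axis.equals(axis):
        return ResponseCurve(axis, rc.gain)
    return ResponseCurve(axis, _interp_counts(rc.axis, rc.gain, axis))
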