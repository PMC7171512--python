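"""Simulated acquisition control: exposure selection and the SNR control loop.

``aec_select_exposure`` mimics an automatic exposure control (AEC): it
picks the shortest integration time that brings the brightest bin of a
single readout to a set fraction (default 50%) of the CCD dynamic range.

``snr_control_loop`` realizes the proposed real-time quality control:
with exposure fixed by the AEC and laser power fixed, single repeats are
acquired and accumulated; after every repeat the accumulated spectrum is
preprocessed and its quality factor computed, and acquisition stops as
soon as the QF target is reached or ``n_max`` repeats have been spent.
Because accumulated Raman and background counts both grow linearly with
``n``, the QF grows like sqrt(n) and the number of repeats needed to
reach a target is approximately ``(qf_target / QF_1)**2`` with ``QF_1``
the single-repeat QF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .preprocess import RollingBallConfig, rolling_ball_decompose, subtract_dark
from .quality import QfConfig, compute_qf
from .simulate import DetectorModel, TissueProfile, sample_measurement
from .spectra import AcquisitionParams, RawSpectrum, SpectrumValidationError

__all__ = [
    "SaturationError",
    "ControlConfig",
    "AecResult",
    "LoopResult",
    "aec_select_exposure",
    "snr_control_loop",
]


class SaturationError(RuntimeError):
    """Raised when the detector saturates even at the minimum exposure."""


@dataclass(frozen=True)
class ControlConfig:
    """User inputs of the SNR control loop: QF target, laser power, n_max."""

    qf_target: float
    laser_power_mw: float
    n_max: int
    dynamic_range_fraction: float = 0.5
    exposure_bounds_ms: tuple[float, float] = (90.0, 600.0)
    qf_config: QfConfig = field(default_factory=QfConfig)
    rb_config: RollingBallConfig = field(default_factory=RollingBallConfig)

    def __post_init__(self) -> None:
        if self.qf_target < 0:
            raise SpectrumValidationError("qf_target must be >= 0")
        if self.laser_power_mw <= 0 or self.n_max < 1:
            raise SpectrumValidationError("laser power must be > 0 and n_max >= 1")
        if not (0 < self.dynamic_range_fraction <= 1):
            raise SpectrumValidationError("dynamic_range_fraction must be in (0, 1]")
        lo, hi = self.exposure_bounds_ms
        if not (0 < lo <= hi):
            raise SpectrumValidationError("exposure bounds must satisfy 0 < lo <= hi")


class AecResult(NamedTuple):
    exposure_ms: float
    reached_target: bool   # False when even t_max misses the dynamic-range goal


class LoopResult(NamedTuple):
    spectrum: RawSpectrum      # accumulated counts with params n = n_used
    qf_trace: np.ndarray       # QF after each repeat, length n_used
    n_used: int
    exposure_ms: float


def aec_select_exposure(
    profile: TissueProfile,
    det: DetectorModel,
    power_mw: float,
    t_bounds_ms: tuple[float, float] = (90.0, 600.0),
    dynamic_range_fraction: float = 0.5,
) -> AecResult:
    """Shortest exposure filling the requested fraction of the dynamic range.

    Expected per-readout counts in the brightest bin are
    ``t * (I_S * (r + a) + dark_rate)``; the AEC solves for the smallest t
    with that value at ``dynamic_range_fraction * full_well``, clamped to
    the exposure bounds.  Saturation at the minimum exposure is an error;
    an unreachable target at the maximum exposure returns ``t_max`` with
    ``reached_target=False``.
    """
    if power_mw <= 0:
        raise SpectrumValidationError("laser power must be > 0")
    t_lo, t_hi = t_bounds_ms
    if not (0 < t_lo <= t_hi):
        raise SpectrumValidationError("exposure bounds must satisfy 0 < lo <= hi")
    peak_rate = float(np.max(power_mw * (profile.raman_rate + profile.background_rate) + det.dark_rate))
    if peak_rate <= 0:
        return AecResult(t_hi, False)
    if t_lo * peak_rate > det.full_well:
        raise SaturationError(
            f"detector saturates at minimum exposure {t_lo} ms "
            f"(expected peak {t_lo * peak_rate:.0f} > full well {det.full_well:.0f})"
        )
    t_star = dynamic_range_fraction * det.full_well / peak_rate
    t = float(np.clip(t_star, t_lo, t_hi))
    return AecResult(t, t_star <= t_hi)


def snr_control_loop(
    profile: TissueProfile,
    det: DetectorModel,
    cfg: ControlConfig,
    seed: int | np.random.Generator | None = None,
) -> LoopResult:
    """Acquire repeats until the QF target is reached or n_max is spent.

    Each iteration samples one repeat from the virtual tissue, adds it to
    the accumulation, subtracts a noise-free scaled dark reference, runs
    the rolling-ball decomposition and recomputes the QF on the full
    accumulated spectrum.  The loop stops at the first repeat where
    ``QF >= qf_target``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = aec_select_exposure(
        profile, det, cfg.laser_power_mw, cfg.exposure_bounds_ms, cfg.dynamic_range_fraction
    ).exposure_ms
    axis = profile.axis
    # the controller knows its detector: noise-free dark expectation per repeat
    dark_per_repeat = np.full(len(axis), t * det.dark_rate)
    accumulated = np.zeros(len(axis))
    trace: list[float] = []
    n_used = cfg.n_max
    for i in range(1, cfg.n_max + 1):
        params_1 = AcquisitionParams(1, t, cfg.laser_power_mw)
        raw, _ = sample_measurement(profile, det, params_1, seed=rng)
        accumulated += raw.counts
        params_i = AcquisitionParams(i, t, cfg.laser_power_mw)
        acc = RawSpectrum(axis, accumulated, params_i, {"n_accumulated": i})
        dark = RawSpectrum(axis, i * dark_per_repeat, params_i, {"kind": "dark"})
        stage = subtract_dark(acc, dark)
        decomposed = rolling_ball_decompose(stage, cfg.rb_config)
        qf = compute_qf(decomposed, cfg.qf_config)
        trace.append(qf)
        if qf >= cfg.qf_target:
            n_used = i
            break
    spectrum = RawSpectrum(
        axis, accumulated, AcquisitionParams(n_used, t, cfg.laser_power_mw),
        {"n_accumulated": n_used},
    )
    return LoopResult(spectrum, np.asarray(trace), n_used, t)
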