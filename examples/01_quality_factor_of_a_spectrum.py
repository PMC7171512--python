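"""Compute the quality factor of a single simulated brain measurement.

Builds a virtual cancer-tissue measurement (5 repeats, 75 ms, 60 mW), runs
the preprocessing chain (dark subtraction, response correction,
rolling-ball background removal) and sums the per-bin Raman SNR over the
1441 and 1659 cm^-1 bands.
"""

import numpy as np

from ramanqf import (
    AcquisitionParams,
    DetectorModel,
    QfConfig,
    apply_quality_threshold,
    compute_qf,
    preprocess_pipeline,
    sample_measurement,
)
from ramanqf.quality import raman_snr_per_bin
from ramanqf.simulate import make_dark_reference, make_response_curve, make_tissue_profile
from ramanqf.spectra import QualityRecord

profile = make_tissue_profile("cancer", seed=1)
detector = DetectorModel()
response = make_response_curve(profile.axis)
dark = make_dark_reference(profile.axis, detector, seed=2)

params = AcquisitionParams(n_repeats=5, exposure_time_ms=75.0, laser_power_mw=60.0)
raw, _truth = sample_measurement(profile, detector, params, seed=3, response=response)

decomposed, processed = preprocess_pipeline(raw, dark, response)
cfg = QfConfig()  # 1441 + 1659 cm^-1 bands, threshold 145
qf = compute_qf(decomposed, cfg)
snr = raman_snr_per_bin(decomposed)
label = apply_quality_threshold([QualityRecord("demo", qf)], cfg.threshold)[0]

print(f"peak per-bin Raman SNR : {snr.max():.2f}")
print(f"quality factor (QF)    : {qf:.1f}")
print(f"QF > {cfg.threshold:.0f}?            : {'high quality' if label else 'low quality'}")
print()
print("The QF sums the shot-noise-limited SNR of the Raman contribution")
print("over the CH2/CH3 (1441) and amide I (1659) bands; spectra above the")
print("calibrated threshold carry enough inelastic-scattering signal for")
print("tissue classification.")
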