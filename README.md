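# ramanqf

Quantitative spectral-quality assessment for tissue Raman spectroscopy,
built for the intraoperative setting: single-point probe measurements of
brain tissue where a fluorescence-dominated background buries the Raman
peaks and where including noise-drowned spectra in a training set
quietly degrades pathology-detection models.

The package is aimed at people building Raman-based tissue-classification
pipelines who need an unbiased, automatic alternative to "does this
spectrum look OK?" — both for retrospective filtering of existing
datasets and for closed-loop control of the acquisition itself.

## The method

Photon detection is Poisson, so the noise in spectral bin *j* is shot
noise on the **total** count there. With Raman contribution *r<sub>j</sub>*
and background *a<sub>j</sub>* (photoelectron rates per ms·mW), a
measurement of *n* repeats, exposure *t* and laser power *I<sub>S</sub>*
has a shot-noise-limited Raman SNR of

```
SNR_j = √(n·t·I_S) · r_j / √(r_j + a_j)
```

and the **quality factor** sums it over preselected tissue bands
(C–C stretch 1087, CH₂/CH₃ 1441, amide II 1553, amide I 1659 cm⁻¹):

```
QF = Σ_{j ∈ bands} SNR_j .
```

A spectrum is high quality when `QF > threshold`, with the threshold
calibrated by ROC against visual quality scores (the sum *qS* of three
reviewers' 1–3 grades; *qS* ≥ 7 = high quality). Around this sit the
four preprocessing steps the decomposition needs (dark subtraction,
intensity-response correction, rolling-ball background removal, SNV
normalization), a quality-gated SVM tissue-classification experiment, a
simulated SNR-controlled acquisition loop, and a synthetic generator of
labeled intraoperative brain datasets that serves as the test bed.

## A worked example

```python
from ramanqf import (AcquisitionParams, DetectorModel, QfConfig,
                     compute_qf, preprocess_pipeline, sample_measurement)
from ramanqf.simulate import (make_dark_reference, make_response_curve,
                              make_tissue_profile)

profile = make_tissue_profile("cancer", seed=1)
detector = DetectorModel()
response = make_response_curve(profile.axis)
dark = make_dark_reference(profile.axis, detector, seed=2)

params = AcquisitionParams(n_repeats=5, exposure_time_ms=75.0, laser_power_mw=60.0)
raw, _ = sample_measurement(profile, detector, params, seed=3, response=response)

decomposed, snv = preprocess_pipeline(raw, dark, response)
print(compute_qf(decomposed, QfConfig()))
```

This prints `184.6...`: the summed per-bin Raman SNR over the 1441 and
1659 cm⁻¹ windows. Against the default threshold of 145 the spectrum is
labeled high quality — at 5 repeats × 75 ms × 60 mW this virtual
measurement collected enough inelastically scattered photons for its
lipid/protein bands to stand clear of the shot noise. The same script
with `laser_power_mw=12` lands near QF ≈ 84: visually plausible, but
too noisy to trust for classification.

The `examples/` directory holds one short narrative script per
capability (run as `python examples/03_roc_threshold_calibration.py`):

| script | what it shows |
|---|---|
| `01_quality_factor_of_a_spectrum.py` | preprocessing chain + QF of one measurement |
| `02_sqrt_n_scaling.py` | QF grows like √n with accumulated repeats |
| `03_roc_threshold_calibration.py` | ROC calibration of the threshold against *qS* (AUC ≈ 0.99) |
| `04_gated_classification.py` | quality gating improves normal-vs-cancer SVM accuracy and stability |
| `05_snr_control_loop.py` | simulated acquisition stopping at a QF target, n ≈ (target/QF₁)² |

A thin CLI mirrors the library for shell use:

```bash
ramanqf simulate ds/ --seed 0           # write a synthetic labeled dataset
ramanqf qf ds/ --out qf.tsv             # QF + quality label per spectrum
ramanqf roc ds/ --plot roc.png          # calibrate the threshold
ramanqf classify ds/ --gate 0 --gate 160
ramanqf acquire-sim --qf-target 280
```

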