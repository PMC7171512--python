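# Methods

## The quality factor

In fingerprint-region (~400–1800 cm⁻¹) tissue Raman spectroscopy the
detected signal is dominated by a smooth background — mostly tissue
autofluorescence plus instrument contributions — that sits one to two
orders of magnitude above the narrow Raman peaks carrying the
biochemical information. Because photon detection is a Poisson process,
the noise in every spectral bin is shot noise on the **total** count,
so a spectrum can have bright, clean-looking background and still carry
no usable Raman information.

Let `r_j` and `a_j` be the Raman and background photoelectron *rates*
(counts·ms⁻¹·mW⁻¹) in bin `j`, and let a measurement accumulate `n`
repeats of exposure `t` (ms) at laser power `I_S` (mW at the sample).
Accumulated counts are `R_j = n t I_S r_j` and `A_j = n t I_S a_j`, and
the shot-noise-limited SNR of the Raman contribution is

    SNR_j = R_j / sqrt(R_j + A_j) = sqrt(n t I_S) · r_j / sqrt(r_j + a_j).

The counts-domain form is what the implementation computes (it is what
preprocessing yields); the rate form makes the `sqrt(n)`, `sqrt(t)` and
`sqrt(I_S)` scaling explicit and drives the simulator's ground truth.
Bins with `R_j + A_j = 0` are assigned SNR 0, the limit of the formula.

The quality factor sums `SNR_j` over every bin inside a set of
preselected tissue bands:

    QF = Σ_{j ∈ bands} SNR_j.

Default bands are the C–C stretch (1087), CH₂/CH₃ deformation (1441),
amide II (1553) and amide I (1659 cm⁻¹) windows, each **center ± 15
cm⁻¹**; the default scoring mode uses the 1441 + 1659 pair, which is
the combination that calibrates best against visual quality review. A
spectrum is "high quality" when `QF > threshold` (strict inequality).
The shipped default threshold of 145 is meaningful only for the default
axis (1000 bins over 400–1800 cm⁻¹) and band windows: the QF is an
extensive quantity — its magnitude scales with the number of bins
summed — so the threshold must be recalibrated (`evaluate.roc_quality`)
for any other instrument, binning or band choice.

Summation is per-bin rather than one value per band. The alternative
reading (one SNR per band) only rescales the QF by the bin count per
band; the ROC calibration absorbs such rescalings, but the numeric
threshold does not transfer between the two conventions.

## Preprocessing

Four steps, in order; the QF is computed from the decomposition after
step 3, i.e. before SNV normalization:

1. **Dark subtraction.** A laser-off reference, rescaled by the ratio
   of exposure products `n·t` (dark counts accumulate with total
   exposure), subtracted and clipped at zero.
2. **Intensity-response correction.** Division by a relative gain curve
   measured on a fluorescence standard. The QF is computed after this
   step, following the processing order; note response correction
   rescales the Poisson statistics bin-by-bin, so post-correction
   counts are "Poisson-like" only up to the gain (a ±15% effect for the
   synthetic gain curve). This is a documented caveat, not corrected
   for.
3. **Rolling-ball background removal.** The baseline is a 1-D
   grey-scale morphological opening with a flat structuring element of
   width `2 × radius` on the wavenumber axis (default radius 50 cm⁻¹:
   larger than tissue Raman peak half-widths of 5–15 cm⁻¹, far below
   the several-hundred-cm⁻¹ curvature scale of the fluorescence
   background). Two moving averages bracket the opening:
   * a **pre-smoothing** of width 18 cm⁻¹ before the opening. Without
     it the erosion tracks the lower envelope of the shot noise and the
     baseline sits ~2 noise standard deviations below the background;
     the recovered Raman counts then inherit a noise-floor offset which
     grows like `sqrt(accumulated counts)` and visibly bends the
     `sqrt(n)` law of the QF. Pre-smoothing (the classical
     "smooth-then-roll" formulation) suppresses this bias while leaving
     peaks (broadened to ≲ 25 cm⁻¹ half-width) well inside the
     opening's removal range;
   * a **post-smoothing** of the element width that removes the
     staircase artifacts of a flat-element opening.
   The smoothed baseline is clipped to the signal, so `a_j ≤ counts_j`
   and `r_j = counts_j − a_j ≥ 0` hold exactly, and `r + a`
   reconstructs the input bit-for-bit.
4. **SNV normalization.** `(x − mean) / populationStd`, with a single
   exact re-centering pass so the zero-mean/unit-std contract holds to
   1e-9 even for inputs spanning many orders of magnitude. Population
   (not sample) standard deviation, fixed for bit-stable tests; at
   N ≈ 1000 bins the difference is negligible. Constant input is a
   `ZeroVarianceError`.

Residual baseline imperfection leaks a small fraction of the curved
background into `r` (≈ 0.3% RMSE of the background maximum on
noise-free synthetic spectra, worst near the background crest). On the
default profiles this contributes roughly 10% of a typical measured QF,
uniformly across quality levels; since the QF threshold is calibrated
on measured QF values, the leak shifts the threshold but not the
discrimination.

## The synthetic data generator

No public intraoperative dataset exists for this kind of measurement,
so the package ships a generator that emulates the acquisition regime
of a hand-held single-point probe study in brain surgery, and every
claim the tests make should be read as a claim about this model:

* **Axis**: 1000 bins, 400–1800 cm⁻¹ (bin width 1.40 cm⁻¹).
* **Raman lines**: Lorentzians (natural line shape) at 1004
  (phenylalanine), 1082/1087 (nucleic acids / C–C stretch), 1300
  (amide III), 1339 (tryptophan), 1441 (CH₂/CH₃), 1553 (amide II) and
  1659 cm⁻¹ (amide I); HWHM 5–13 cm⁻¹; amplitudes put integrated Raman
  at < 5% of the total signal (background dominance, mirroring the
  regime where a processed Raman trace must be amplified ~50× to be
  visible over its background).
* **Background**: a two-component Gaussian mixture (σ ≥ 380 cm⁻¹)
  plus offset, with log-normal amplitude variation at the patient level
  (σ = 0.25) and point level (σ = 0.15). Optional shape jitter
  (component weights/centers) exists but defaults to off.
* **Classes**: cancer tissue scales the lipid-dominated bands down
  (1441 × 0.94, 1659 × 0.97, amide III 1300 × 0.84) and the nucleic-acid
  and amino-acid bands up (1004 × 1.20, 1082/1087 × 1.14, 1339 × 1.16);
  "infiltrated" sits halfway. The headline 1441/1082 band-ratio shift
  is ~16% — deliberately subtle, so that classification succeeds on
  clean spectra and degrades on noisy ones. Per-peak log-normal
  amplitude jitter (σ = 0.02) models biological variability.
* **Detector**: expected counts per bin are
  `n t I_S (r + a) gain + n t dark` (dark rate 0.02 counts/ms/bin),
  Poisson-sampled, plus Gaussian read noise (σ = 2 counts/readout,
  deliberately negligible against shot noise). Counts clip at the full
  well (65535, a 16-bit CCD) per readout; clipping is flagged, never
  silent.
* **Acquisition protocol**: 44 patients, Poisson(7) acquisition points
  each, one measurement per point accumulating n ∈ {5…10} repeats,
  exposure t ∈ {50, 75} ms, laser power 10–75 mW. Power is drawn from
  one of two protocol arms — conservative 10–18 mW (used near eloquent
  or bleeding-prone sites) or 55–75 mW — each equally likely. The
  bimodal power is the generator's main quality driver: the low-power
  arm produces genuinely noise-dominated spectra, the high-power arm
  clean ones, which is what gives quality gating something real to
  remove. Cancer:normal ratio ≈ 1:1.75; class and power are assigned
  independently.
* **Surrogate reviewers**: three independent graders each map the true
  mean in-band SNR `s` (over the 1441/1659 windows) through the
  saturating logistic `grade = 1 + 2 s² / (s² + 4.5²)` with Gaussian
  grading noise (σ = 0.15), clipped and rounded to 1–3; `qS` is their
  sum (3–9), `qS ≥ 7` meaning high quality. Saturated measurements are
  graded at the floor — a clipped spectrum looks unusable regardless of
  its photon dose. The midpoint 4.5 centers the ambiguous zone on the
  dataset median so both labels are ~50% prevalent; at `s = 12` the
  probability of `qS ≥ 7` exceeds 0.8 by construction. Reviewer noise
  has no empirical anchor (inter-reviewer agreement is not published
  for this protocol) and is the model's most arbitrary constant.

What the generator does **not** model: photobleaching of the
fluorescence background across repeats, cosmic-ray spikes, tissue
heating (safety is represented only by `n_max` and the exposure
bounds), wavelength-dependent absorption by hemoglobin/melanin, probe
pressure or contact variation, and any spatial correlation between
acquisition points. Passing tests therefore demonstrate internal
consistency of the method and its qualitative behavior in a realistic
noise regime — not clinical performance on real tissue.

## Threshold calibration and the gated-classification experiment

`roc_quality` sweeps the threshold over 0 and every distinct QF value,
labels `QF > threshold` as high quality, and scores against
`qS ≥ 7`. The operating point maximizes Youden's J, ties broken toward
higher specificity (the criterion "optimizes both sensitivity and
specificity" is not otherwise pinned down). AUC is the rank statistic
(monotone-transform invariant).

`train_gated_classifier` keeps normal/cancer measurements with
`QF > gate`, uses the SNV spectra as features, and runs a pipeline of
standardization → L1-regularized linear-SVM feature selection (bins
with non-zero coefficients survive) → linear SVM. Hyperparameters (the
classifier C over {0.01, 0.1, 1, 10, 100} and the selector C over
{0.1, 1}) are grid-searched on the training folds. Cross-validation is
five-fold, **grouped by patient** (co-located spectra share acquisition
conditions and must not straddle a train/test split) and
**class-stratified** across groups, since at ~11 cancer spectra per
fold an unstratified split makes per-fold sensitivity meaningless.
Whether the original experiment grouped folds by patient is unknown;
grouping is the conservative choice. Both raw and balanced accuracy are
reported (they differ little at the 1:1.75 ratio).

Across-fold standard deviations at this dataset size (~300
measurements, ~150 after gating) sit near their binomial floors
(0.04–0.07); the variability comparison between gated and ungated
models is therefore estimated from repeated cross-validation (3
different fold assignments averaged) rather than a single split.

## The acquisition controller

`aec_select_exposure` solves `t* = f · full_well / max_j(rate_j)` — the
shortest exposure putting the brightest bin at fraction `f` (default
0.5) of the dynamic range — clamped to bounds (default 90–600 ms).
Expected dark counts are included in the rate. Saturation at the
minimum exposure is an error; an unreachable target returns the maximum
exposure with a flag.

`snr_control_loop` fixes power, sets `t` by AEC, then repeatedly
samples one repeat, adds it to the accumulation, subtracts the
(noise-free, model-known) dark expectation, re-runs the rolling ball on
the **full accumulated spectrum** and recomputes the QF; it stops at
`QF ≥ target` or `n = n_max`. Recomputing on the accumulation (rather
than averaging per-repeat QFs) is what makes the trace follow the
`sqrt(n)` law, and the expected stopping time is `≈ (target/QF₁)²`
repeats.

## Numerical and interface choices

* On-disk format: two-column delimited text (wavenumber, counts) with a
  JSON sidecar for `n`, `t`, `I_S` and metadata; floats at 17
  significant digits make round trips bit-exact. JCAMP-DX (AFFN
  `(XY..XY)` and `(X++(Y..Y))` tables) is read-only import. Reading
  sorts the axis ascending and averages duplicate wavenumbers.
* Resampling is linear interpolation; extrapolation is an error.
* Degenerate inputs fail loudly: negative counts, non-monotone axes,
  non-positive gain, zero-variance SNV input, rolling-ball radius under
  two bin widths, empty band selections, single-class ROC input, and
  gates that leave too few measurements all raise typed exceptions.
* All randomness flows through `numpy.random.Generator` objects seeded
  from user-supplied integers; dataset generation is a pure function of
  its config, and the manifest is byte-identical across runs with the
  same seed.
* Experiment sizes in the test-suite and acceptance script (100
  Monte-Carlo replicates for the sqrt(n) law, 10⁴ Poisson draws for the
  shot-noise oracle, 10 simulation seeds × 3 CV repeats for the gating
  comparison, 100 control-loop runs) are chosen so each statistical
  assertion has comfortable margin over its sampling error.

## Known limitations

* The shot-noise SNR treats the post-response-correction counts as
  Poisson; a strongly varying gain curve would bias the QF.
* The rolling-ball background leaks ~1% of a strongly curved
  background into the Raman channel near its crest; polynomial or
  asymmetric-least-squares baselines are out of scope.
* The QF is an extensive, instrument-specific quantity; thresholds do
  not transfer between spectrometers, bin widths or band conventions
  without recalibration.
* The class-balance property under gating is a noisy statistic at this
  dataset size (the gated cancer arm holds ~50 measurements, a ~12%
  relative binomial error) and can exceed its nominal 25% band for
  unlucky datasets even though the gate is class-neutral by design.
* Surrogate reviewers are a monotone-map-plus-noise model; real visual
  grading has structure (anchoring, fatigue, criteria drift) this does
  not capture.
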