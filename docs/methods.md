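# Methods

`stereomrs` is a synthetic testbed for a complete edited-MRS study of
visual-cortex neurochemistry: it generates MEGA-PRESS-style acquisitions and
random-dot-stereogram (RDS) stimuli with known ground truth, quantifies
GABA+ and Glx from the simulated spectra, and runs the study's statistical
machinery (static paired comparisons, dependent-correlation structure,
condition × order ANOVA, sliding-window cluster-permutation dynamics,
psychometric fitting).  This note records the models, the defaults and why,
and the places where a genuine design choice had to be made.

## Spectral simulation (`spectra_sim`)

Spectral editing alternates editing-pulse ON and OFF transients; coupled
resonances (the 3-ppm GABA+ multiplet, the 3.8-ppm Glx complex) survive in
the ON−OFF difference while uncoupled singlets (tCr, choline) cancel.  The
simulator works directly in the spectral domain: each transient is a sum of
peak models (FWHM-parameterised Gaussian, Lorentzian, or pseudo-Voigt
shapes) rendered on a ppm axis, plus white noise.  Time-domain FID physics,
eddy currents, and residual water are out of scope — everything downstream
consumes spectra.

- **Axis.** 2,048 points over a 2,000-Hz width at 123.25 MHz (3T proton),
  centred on water at 4.7 ppm.  These are conventional 3T values; the
  acquisition bandwidth of the motivating experiment is not public, so the
  axis is configurable.
- **Editing classes.** `edited` peaks appear only in ON (hence with full
  amplitude in the difference); `unedited` peaks cancel exactly; `inverted`
  peaks appear with amplitude −2a in the difference (the documented sign
  convention for the NAA-like resonance).
- **Doublets.** GABA+ and Glx are simulated as double Gaussians (two equal
  sub-peaks; defaults: GABA+ at 3.00 ppm, separation 0.11 ppm, sub-peak FWHM
  0.08 ppm; Glx at 3.75 ppm, separation 0.10, FWHM 0.06) so the
  double-Gaussian quantification model is well-posed.  Co-edited
  macromolecules are folded into the GABA+ amplitude, since GABA+ is by
  definition GABA plus macromolecules.
- **True ratios.** `default_peaks(gaba_tcr, glx_tcr)` converts target area
  ratios (relative to the analytic area of the simulated tCr peak on the
  non-edited spectrum) into sub-peak amplitudes, so simulated truth and the
  quantified quantity coincide by construction.  Default truths
  (GABA+:tCr = 0.12, Glx:tCr = 0.15) sit in the range typical of occipital
  edited-MRS ratios.
- **Choline lineshape.** Choline (3.20 ppm) is rendered as a pure Gaussian
  with 0.05-ppm FWHM.  A heavy Lorentzian choline tail bleeds into the tCr
  fit window and biases the single-peak tCr fit by ~10%; with a Gaussian
  choline and the asymmetric tCr window (below), the noiseless end-to-end
  bias is < 0.2%.
- **Drift.** Frequency drift is a per-transient N(0, σ_f) shift of all peak
  centres (σ_f in Hz); phase drift is a zero-order rotation of the analytic
  (Hilbert-transform) spectrum by N(0, σ_φ) degrees.  Only the real part is
  stored, as in the interchange format.
- **Noise.** Per-point white noise, default σ = 0.02 against a tCr height of
  1.0 — chosen so the GABA+ fit error at 256 transients is ~5%, matching
  routine edited-MRS quality.

### Cohorts

`CohortConfig` encodes the study design: 20 subjects, four acquisitions
each (rest, two active conditions in counterbalanced order, half-length
second rest).  Per-subject baselines are the population mean times
(1 + N(0, 0.10)); each acquisition adds fractional jitter
`within_subject_sd` (default 0.04, giving a paired-design effect size
d_z ≈ 0.7 at the default −4% GABA+ condition effect and hence ~85% power at
n = 20 — in the regime of the motivating study's reported t values); rest
acquisitions can receive extra variance (`rest_extra_sd`, default 0) to
emulate an uncontrolled rest state.  Condition effects are fractional
shifts applied to the mixed-polarity condition (defaults −4% GABA+, +2%
Glx).  An optional per-window `effect_profile` scales the edited-peak
amplitudes pair-by-pair for time-resolved simulations.  Counterbalancing
alternates order assignment, so even cohorts split exactly and odd cohorts
differ by one (with a warning).

### Vernier trials

Binary left/right judgements are Bernoulli draws from
P(right | x) = lapse/2 + (1 − lapse)·Φ((x − bias)/σ), on seven offsets
spanning ±6.4 arcmin.

## Stimuli (`rds`)

A 12° × 12° field at 108 dots/deg², dots with a Gaussian luminance profile
of 0.07° FWHM on a 0.5 background, black/white per polarity condition; four
annular wedges (70° polar width, 20° gaps) around a 0.6°-radius aperture
carry the disparity: wedge dots are drawn at ±disparity/2 per eye (default
10 arcmin; the 6-arcmin variant reported elsewhere for the same stimuli is
a plain config value), other dots are identical between eyes.  Later dots
occlude earlier ones; occlusion is resolved per pixel by placement order.
Dots shifted beyond the field are clipped, keeping the cyclopean position
fixed.

- **Wedge extent.** The wedge set spans a 10°-diameter disc (radial extent
  4.4° beyond the aperture).  This is the geometry consistent with the
  measured interocular row correlation of these stimuli: rows crossing the
  wedges are decorrelated by the disparity (the ~6.7-px shift at
  10 arcmin/40 px-per-degree exceeds the dot autocorrelation width), so the
  mean row correlation ≈ 1 − (wedge area fraction) = 1 − 0.418 = 0.58, as
  observed.  Reading the wedge extent as 10° per wedge would push the
  annulus past the field corners and predict r ≈ 0.2.
- **Rendering resolution** defaults to 40 px/degree.  The correlation and
  coverage statistics are checked at this default and are mildly
  resolution-sensitive; both are recomputed, not hard-coded.
- **Coverage statistic.** A pixel is "covered" if it lies within a disc of
  diameter k·FWHM of some dot centre.  k was calibrated once from the
  Poisson coverage identity 1 − exp(−λ·π(k·FWHM/2)²) = 0.38 at the default
  density, giving k = 1.0724, and frozen.
- **Row correlations** are Pearson r on raw luminance per horizontal pixel
  row; zero-variance rows are NaN and excluded from averages.  The
  condition comparison averages rows across images within condition
  (optionally binned to 96 y-positions) and applies a paired t across rows
  (df = rows − 1).
- **Run protocol.** Per presentation: fresh uniform wedge rotation in
  [0°, 90°) (the layout is 4-fold symmetric), disparity sign reversal every
  five presentations, and polarity alternation (white/black) across
  presentations in the single-polarity condition.

What the generator does *not* emulate: the vergence-stabilising surround
grid, presentation timing, projector polarization cross-talk, and display
gamma.  Passing correlation/coverage checks therefore validates the
geometry and statistics of the stimulus construction, not its photometry.

## Quantification (`megapress_quant` → `quant`)

Per acquisition:

1. **Frequency/phase correction.**  Each transient is registered to the
   mean spectrum of *its own edit label* over a window spanning the
   creatine and choline peaks (3.03/3.20 ppm ± 0.18).  Label-specific
   templates matter: ON transients carry the edited GABA+ signal underneath
   creatine, and a shared template registers the two labels systematically
   differently, leaving subtraction artifacts at 3 ppm.  The shift is found
   by maximising the magnitude of the complex (analytic-signal) correlation
   on a half-point grid with parabolic refinement; the zero-order phase is
   the argument of that correlation; both are applied in one exact FFT
   sub-sample shift of the original analytic signal (repeated linear
   interpolation would broaden the peaks).  Each label's mean is then
   pinned to the nominal choline position — choline is free of edited
   signal in both labels, so the pinning cannot introduce ON/OFF
   misalignment bias.  (An explicit ON→OFF phase alignment over the
   choline window exists behind a flag but is off by default: the
   long-range dispersion tails of the 3-ppm GABA+ doublet bias it by a few
   degrees, which costs more than the ~0.4° residual it would remove.)
   Transients whose reference region stays below 5× the noise floor are
   flagged and left uncorrected.  The SD of the per-transient shifts (Hz)
   is the reported frequency drift.

   Registering against noisy single transients has a known cost: part of
   the noise is aligned to the template, which inflates the edited signal
   in the difference spectrum.  At the default SNR this biases GABA+:tCr
   by ≈ +3–4% (Glx is unaffected); the bias is constant across
   acquisitions, so paired within-subject comparisons are unaffected, and
   the drift-robustness test bounds it at 5%.
2. **Averaging.**  difference = mean(ON) − mean(OFF); the non-edited mean
   (= mean OFF) carries the tCr reference.
3. **Fitting.**  GABA+ (2.79–3.21 ppm) and Glx (3.55–4.00 ppm) on the
   difference: two Gaussians + linear baseline, by trust-region nonlinear
   least squares; one FWHM shared between the sub-peaks by default
   (stabilises low-SNR fits; component identifiability is explicitly not
   promised — the summed area is the quantity used).  Initialisation:
   centres at the window maximum ± half the nominal doublet separation,
   amplitude from the data height, FWHM from a 3-point width estimate;
   cost tolerance 1e−8.  tCr (2.85–3.12 ppm, stopping short of the choline
   shoulder) and unsuppressed water (4.2–5.2 ppm, from a separate
   16-transient water acquisition) use a single pseudo-Voigt + linear
   baseline.  Non-convergence and degenerate windows yield flagged results,
   never exceptions.
4. **Fit error** = SD of the fit residuals ÷ fitted peak height (height,
   not area, is the default "amplitude"; switchable).
5. **Referencing.**  Ratios of fitted areas: GABA+:tCr, Glx:tCr, and
   optionally the water-referenced variants.  No relaxation corrections are
   applied to water referencing.
6. **CSF correction.**  C_corr = C_meas / (f_GM + f_WM), applied to the
   final ratios (applying it to raw intensities before ratioing would
   cancel — the correction is only meaningful if the reference compartments
   differ, which this model does not represent).

## Dynamics (`dynamics`)

The sliding window is 128 transients (64 ON/OFF pairs) stepped one *pair*
at a time — stepping by single transients cannot keep the window
ON/OFF-balanced, so pair-stepping is used and a 256-transient acquisition
yields 65 windows.  Each window is averaged, subtracted and fitted exactly
as a full acquisition (cumulative sums make the window means O(1)).

**Outlier screening** removes values > 4 SD from the cross-subject mean at
each time point (strict inequality).  The mean and SD include the tested
value, so with n subjects the attainable |z| is capped at (n−1)/√n (≈ 4.25
at n = 20): clean Gaussian data essentially never trips the rule, and only
gross quantification failures are removed — consistent with near-zero
removal rates in practice.

**Cluster-mass permutation test.**  Per window, a paired t on
pairwise-complete subjects (windows with < 50% complete pairs are
excluded); candidate clusters are maximal runs of consecutive windows with
two-sided p < 0.05 (the cluster-forming rule had to be chosen; this is the
standard choice), scored by Σ|t|.  The null shuffles condition labels by
flipping each subject's paired difference independently — exact for a
two-condition within-subject design — with full enumeration when
2^n ≤ n_perm.  The default null statistic is the *maximum* cluster mass per
permutation (controls family-wise error); pooling all cluster masses is
available as `null_statistic="all"`.  Clusters below the 95th percentile of
the null are disregarded; corrected p is the fraction of the null at or
above the observed mass.  Because windows overlap heavily, neighbouring t
values are strongly autocorrelated; the permutation scheme preserves that
structure exactly, so no further smoothness correction is applied.
Calibration at 500 null cohorts × 1,000 permutations puts the family-wise
error within the binomial band around 5%.

`simulate_null_window_cohort` provides window-level null cohorts (boxcar-
averaged white noise) for calibration studies without re-running spectral
fits.

## Group statistics (`group_stats`)

- **Paired t** (df = n − 1), listwise over complete pairs; zero-variance
  differences are flagged rather than inflated.
- **Dependent correlations.**  Comparing r(x,y) with r(x,z) on the same
  subjects uses Steiger's (1980) z on Fisher-transformed correlations with
  the Dunn–Clark pooled-r covariance term.  A within-subject permutation
  (swap the standardised y and z values of random subjects) is implemented
  as the assumption-light verification route.  Both hold their 5% level at
  n = 20; the analytic z runs a few percentage points more powerful than
  the |Δr| permutation at strong alternatives (measured gap ≈ 6 points at
  population correlations 0.6/0/0), which the tests document rather than
  hide.
- **2 × 2 split-plot ANOVA** (condition within, order between), computed
  from sums of squares.  The textbook decomposition tests within effects on
  df (1, N − 2).  Reporting conventions that quote F(1, N − 1) for the
  condition effect in an N-subject design correspond to ignoring the order
  factor, in which case F is exactly the squared paired t; both conventions
  are computed (`convention="textbook" | "pooled"`).
- **Psychometric fit.**  Bernoulli maximum likelihood of
  Φ((x − μ)/σ) with lapse fixed at 0 by default (free lapse ≤ 0.1
  optional); probit-regression initialisation; complete separation is
  flagged (σ unidentified at the bound).

## Pipeline (`pipeline`)

`run_pipeline(RunConfig)` chains everything for one synthetic cohort and
writes cohort/truth/QC/behaviour tables, group-stats and dynamics JSON, and
a manifest with derived seeds and SHA-256 hashes of every output; the same
config reproduces every file bit-for-bit.  Every stochastic stage receives
a seed derived from the run seed via `SeedSequence`.  The second rest
acquisition is simulated at half length (128 transients) and quantified
identically.  All report output is labelled synthetic.

## Problem sizes in tests

The test suite exercises full-size acquisitions (256 × 2,048) where the
claim concerns accuracy at the standard acquisition size, and reduced sizes
chosen for statistical adequacy elsewhere: 64-transient/1,024-point
acquisitions for the 100-replicate pipeline type-I calibration (8-subject
null cohorts; rejection counted against the exact binomial band),
window-level null cohorts for the 500-replicate family-wise-error
calibration, and 6-subject cohorts for the end-to-end orchestration tests.

## Known limitations

- The spectral model has no baseline distortions, residual water, lipid
  contamination or macromolecule baseline; quantification accuracy on real
  spectra will be worse than the recovery benchmarks suggest.
- Zero-order phase correction only; first-order phase is out of scope.
- The stimulus photometry (gamma, polarization cross-talk) is idealised;
  coverage and correlation targets are geometry checks.
- The ANOVA assumes two within levels and two groups — exactly the study
  design, nothing more general.
- Absolute quantification (mM, relaxation-corrected) is deliberately not
  implemented; only ratio measures are produced.
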