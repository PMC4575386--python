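# Methods

This note records the models, defaults and numerical choices behind
`toxprint`, and what the synthetic validation does and does not establish.

## Forward model of an intact-cell spectrum

A simulated spectrum on the uniform grid m/z 2,000–20,000 is

  I(m) = Σ_k h_k · exp(−(m − μ_k')² / 2σ_k²) + B(m) + ε(m)

* **Peaks.** Gaussian, with width growing linearly in mass
  (σ = m/2355 + 1 Da, i.e. FWHM ≈ m/1000 + 2.4 Da), the simplest shape
  consistent with linear-TOF resolution broadening toward high mass. Peak
  height h_k = base abundance × fold-change(toxin, concentration) ×
  lognormal replicate factor (CV 0.18 by default) — independent biological
  experiments scatter multiplicatively, and this is the only
  replicate-to-replicate abundance variability in the model.
* **Baseline.** B(m) = A·exp(−(m − 2000)/λ) + c with A = 800 mV,
  λ = 1500 Da, c = 20 mV: chemical/matrix noise dominating the low-mass
  end, a small flat residual elsewhere.
* **Detector noise.** Additive Gaussian, σ = 10 mV. A 600-shot averaged
  acquisition justifies treating shot noise as Gaussian and spectrally
  white; no shot-level structure is modelled.
* **Calibration drift.** Per spectrum, an affine map s ↦ a + b·s acting on
  s = √(m/z) (TOF time is proportional to √(m/z)), with b − 1 ~ N(0, 5e-5)
  truncated at ±1e-3 and a ~ N(0, 0.005 √Da). Typical mass error is a few
  tenths of a Da to ~2 Da at the high-mass end — below half the matching
  tolerance, so alignment still works even uncalibrated.
* **Grid.** One channel = one grid sample; default step 0.125 Da
  (144,001 channels). The digitizer rate of the original instrument is
  unknown; 0.125 Da is chosen so that the processing defaults quoted in
  channels (below) are physically consistent: with the 51-channel smoothing
  window (6.4 Da) a 3:1 height-ratio peak pair 14 Da apart — the closest
  spacing in the marker panel (4562/4576) — retains two local maxima
  (valley/apex transmission factor 0.135 < 1/(1+3)), whereas a 1 Da step
  would make the same window 51 Da wide and merge those pairs outright.

The default truth panel holds exactly 15 peaks at the marker masses
4562–15,292 Da. Fold-changes at the comparison concentrations (copper
sulfate 9 mg/L, acridine 150 µM, BNF 50 µM) are 2 (↑\*), 3 (↑\*\*), 0.5
(↓\*) or 1/3 (↓\*\*) by annotation level, with log-fold scaling linearly in
concentration across each series — a graded, monotone response. Base
abundances are drawn once per model seed from U(3000, 9000) mV, so that
after smoothing attenuation the processed apexes sit comfortably in the
instrument's >200 mV working range.

**What the generator does not emulate:** isotope structure, adducts and
multimers, matrix clusters, cell-count/spotting effects, peak-shape
asymmetry, correlated (1/f) noise, and drifts in peak *width*. Passing the
recovery suites therefore shows the pipeline is correct under the stated
statistical structure, not that it is robust to every artifact of real
acquisitions.

## Preprocessing

* **Smoothing**: centred moving average, width in channels rounded up to
  odd (default 50 → 51); edges use shrinking windows. This preserves total
  ion current exactly for interior-supported signal.
* **Baseline**: rolling minimum followed by rolling mean of the same width
  (default 100 → 101 channels). The minimum slides under peaks narrower
  than the window; the mean removes the staircase. On a peak-free
  exponential baseline with decay ≫ window span the error is the one-sided
  lag, ≈ A·(1 − e^(−w/λ)) < 2% of amplitude. Subtraction clips at zero and
  reports the clip count.
* **Noise**: rolling MAD (window 501 channels) of the baseline-subtracted
  signal × 1.4826, floored at machine epsilon — robust to sparse peaks.
* **Recalibration**: reference masses are consensus clusters present in a
  majority of spectra, thinned to n_refs = 10 by greedy farthest-point
  selection so they span the mass range; each spectrum's peak masses are
  regressed (observed → reference) as an affine map in √(m/z) and corrected
  by least squares. Matching tolerance max(2 Da, 500 ppm). The fit strictly
  reduces the RMS reference residual and is idempotent.

Order of operations: smooth → baseline → subtract → detect → calibrate →
align. The instrument software's internal order is unknown; this order lets
detection work on clean signal while calibration works on detected peaks.

## Peak detection

Local maxima (plateau ties resolve to the lowest-mass channel) passing both
S/N ≥ 3 and apex ≥ 200 mV, where both thresholds apply to the
smoothed, baseline-subtracted signal — whether the original 200 mV referred
to pre- or post-processing amplitude is unknowable, and post-processing is
the conservative choice. Maxima closer than the local FWHM merge into the
taller one; the reported mass is the intensity-weighted centroid over
apex ± 3 channels. Raising either threshold can only remove peaks.

## Alignment and differential statistics

Pooled peak masses are single-linkage clustered (sorted gaps cut where they
exceed max(2 Da, 500 ppm·m)); consensus mass = cluster median; a sample
absent from a cluster contributes 0 mV, which keeps the paired tests
defined (this convention is switchable in principle but is the default
because dropping pairs would bias power peak-by-peak). 2 Da + 500 ppm
exceeds the simulated drift yet stays far below the closest panel spacing
(14 Da).

Per peak × toxin the treated arm (comparison concentration) meets its
replicate-matched control: one Grubbs pass per arm (two-sided, α = 0.05,
critical value G = (n−1)/√n · √(t²/(n−2+t²)), t = t_{α/2n, n−2}) removes at
most one replicate pair; fewer than 3 surviving pairs marks the peak
untestable rather than dropping it. The paired t-test is two-sided; marks
are \* (p<0.05) and \*\* (p<0.01) with **no multiple-testing correction**
across the 15 peaks — the tabulated fingerprint this mirrors reports
per-peak marks, and users should expect ≈1 false mark per 21 null cells.
The Grubbs screen inflates the realised per-test level slightly (measured
≈0.059 at nominal 0.05 with n = 6); this is a property of
outlier-screen-then-test procedures generally, documented rather than
corrected.

## Dose–response

4PL fit by Levenberg–Marquardt on log-dose with the dose axis internally
normalised by its geometric mean, which makes EC50 unit-equivariance
structural (remaining discrepancy under unit changes is ~1e-8 relative:
the flat likelihood valley amplifies 1-ulp differences in log(c·d)).
Initialisation from data quartiles with a small multistart over Hill
slopes; top/bottom unconstrained. The 95% CI is asymptotic on log EC50
(t-quantile × SE from the Jacobian covariance), exponentiated — the
familiar asymmetric interval; measured coverage ≈95% at 5% response noise
with 8 doses × 4 replicates. Zero-dose control wells anchor the
normalisation (percent = 100·(signal − blank̄)/(control̄ − blank̄)) and do
not enter the log-dose fit. The outlier screen is ROUT-flavoured: soft-L1
robust fit, MAD residual scale, per-point t-probabilities screened by
Benjamini–Hochberg at Q = 1%, refit without flagged points (declined when
>30% flag). The exact commercial procedure is proprietary; this is an
emulation of its documented behaviour, not a reimplementation.

Dunnett's many-to-one test uses Monte-Carlo critical values: 100,000 seeded
draws of max_i |T_i| under the null (group means ~ N(0, 1/n_i), pooled
χ²_df scale), cached per group configuration; adjusted p-values are tail
fractions of the same draws. This handles unbalanced groups without tables
and agrees with an independent implementation to within MC resolution
(±0.01).

## Fingerprint PCA

The change matrix is peaks × treatments of treated/control mean-abundance
ratios, plus a pooled-control column (ratio 1). Ratios are log-transformed
by default before PCA (fold data are multiplicative; the flag exists
because the original transform is unstated), columns are mean-centred,
unit-scaling is off by default. The decomposition is a dense SVD with a
deterministic sign convention (largest-magnitude loading positive per
component), hence bit-for-bit reproducible. Toxin specificity is tested as
pairwise linear separability of the toxins' (PC1, PC2) loading arrows
through the origin. The printed variance split of the original study
(59%/19%) is not a recovery target — it depends on the authors' raw
abundances, which were never published; the synthetic analog lands around
55%/34% under the default truth.

## Problem sizes used in validation

Detection recall/precision: 50 spectra of ~30 strong peaks each. Marker
concordance: the 4-condition × 6-replicate comparison design. Null
calibrations: 10,000 trials (t-test, Grubbs). EC50 CI coverage: 500
simulated plates. Separability: 10 full-pipeline experiments on the
complete 12-condition design. These sizes give stable estimates (binomial
SE ≲ 1%) while keeping the whole suite around a minute.

## Known limitations

* Abundances after preprocessing are attenuated relative to the raw apex
  (boxcar smoothing plus partial baseline absorption under broad high-mass
  peaks); all differential statistics are ratio-based and unaffected, but
  absolute mV values in the consensus table underestimate raw apex heights.
* The paired design assumes treated and control replicates share an
  experiment batch index; designs without such pairing need the unpaired
  variant, which is not provided.
* mzML support is read-only and covers the plain interchange subset
  (first profile spectrum, 32/64-bit floats, optional zlib).
* Peaks co-eluting closer than the local FWHM merge by design; the marker
  panel's 14 Da minimum spacing is safely above that at the default grid.
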