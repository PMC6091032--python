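# Methods

## Energy-expenditure model

All gas rates cross the public API in mL/min; conversion to L/min happens
once, inside `vco2ree.weir`. The nitrogen-free two-term Weir equation is
used throughout:

    REE = (a·VO₂ + b·VCO₂) × 1440,    a = 3.941 kcal/L O₂, b = 1.106 kcal/L CO₂.

The VCO₂-only estimator substitutes VO₂ = VCO₂/RQ at a fixed assumed RQ,
giving the per-litre multiplier m(RQ) = a/RQ + b: 6.361 at RQ 0.75, 6.032
at 0.80, 5.742 at 0.85, 5.534 at 0.89. m is strictly decreasing in RQ, so
for a fixed reference the estimator's bias rises monotonically as the
assumed RQ falls, while correlation-type metrics are invariant (a fixed RQ
is a positive rescaling). The clinical shorthand `5.5 × VCO₂ × 1.44` is the
RQ-0.89 multiplier with 5.534 → 5.5 and 1440/1000 → 1.44; it is treated as
a presentation of that estimator, not a separate one. Coefficients are
configurable (`WeirCoefficients`) for sensitivity analysis; urinary
nitrogen correction and food-quotient-based RQ are out of scope.

RQ sanity bounds: inputs with RQ outside (0.3, 2.0) are rejected — such
values indicate device or unit errors, not physiology.

## Synthetic cohort

No patient-level data accompany the validation setting this package
emulates, so `vco2ree.cohort` generates cohorts whose *marginal* structure
matches the reported one: 80 patients; measurements per patient with median
3 and IQR 2–7; reference REE 2059.5 ± 491.7 kcal/day; measured RQ
0.75 ± 0.07; and a pooled correlation of ≈0.51 between the ventilator-based
estimator and the reference.

Generative chain, per measurement:

1. **REE.** Patient random effect + within-patient noise, both normal,
   splitting the total variance 60/40 between/within (`between_patient_frac`;
   the split is not identified by marginal moments — 60/40 is a plausible
   ICU value and is configurable). Draws at or below a 500 kcal/day floor
   are resampled.
2. **RQ.** Truncated normal on [0.60, 1.10], independent across
   measurements. The *parent* mean/SD are solved numerically so the
   truncated distribution has exactly the configured moments: naive
   truncation of N(0.75, 0.07) at these bounds would shift the mean by
   +0.003 and shrink the SD by ~4.5%, visibly corrupting moment recovery at
   cohort scale.
3. **True VCO₂.** The Weir relation is inverted with VO₂ = VCO₂/RQ:
   VCO₂ = 1000·REE / (1440·m(RQ)). The IC device observes VO₂ and VCO₂
   exactly (IC is the reference; its own error is not modelled).
4. **Ventilator trace.** Records every 5 min over the 6 h preceding each
   measurement: true VCO₂ × `vent_bias` × stationary lognormal AR(1) noise
   (mean 1, lag-1 coefficient 0.8 on the log scale, relative SD
   `vent_noise_sd`).

Two defaults are calibrated rather than free:

- **`vent_bias` = 1.0887.** The chain above pins E[true VCO₂] ≈ 224.6
  mL/min once the REE and RQ distributions are fixed, while the emulated
  setting reports ventilator 6-h block means of 244.5 mL/min. The ratio is
  the implied multiplicative disagreement between ventilator and
  calorimeter CO₂ measurement, computed analytically by
  `implied_vent_bias()` (quadrature over the RQ distribution) and frozen.
- **`vent_noise_sd` = 1.257,** set once with `tune_vent_noise_sd()` so the
  pooled estimator–reference Pearson correlation on a large default cohort
  is ≈0.51. Block averaging of 72 AR(0.8) records attenuates this
  single-record noise by ≈√8, leaving an effective block-level noise CV of
  ≈0.44.

**A deliberate non-recovery.** With the correlation pinned at 0.51, the
block-VCO₂ SD comes out at ≈114 mL/min, not the reported 85.9. The two
targets are mutually exclusive under any multiplicative-noise model: with
reference CV 491.7/2059.5 = 0.239, a block CV of 85.9/244.5 = 0.351 forces
a correlation of ≈0.68, and conversely correlation 0.51 forces block CV
≈0.47. The generator honours the correlation (which drives every agreement
metric downstream) and lets the block SD float; the moment-recovery
acceptance test asserts the reported SD anyway and is expected to fail on
exactly that clause, documenting the inconsistency rather than hiding it.

Measurements-per-patient counts are drawn from a discrete distribution on
1..15 fit by coarse grid search (geometric body + uniform tail) to the
median/IQR targets with a 0.01 CDF margin; within this family the mean is
≈4.8, so a default 80-patient cohort yields ≈380–400 pairs. Randomness is
one root `SeedSequence` with per-patient child streams: enlarging a cohort
never changes existing patients.

What the generator does **not** emulate: calorimeter measurement error,
diurnal or illness-course REE trends, informative measurement timing
(sicker patients measured more often), ventilator drift or gaps, and
within-patient RQ autocorrelation. Passing tests therefore demonstrate the
*pipeline's* correctness and the reported statistical structure, not
clinical performance on real patients.

## Pairing

Each IC measurement at time t is matched to the arithmetic mean of the
ventilator records in the half-open window [t − 360 min, t): the window
strictly precedes the assessment, and half-openness prevents a record
stamped at t from being double-used. Coverage = records present / records
expected at the trace's nominal step; windows under `min_coverage` = 0.8
(a completeness rule of this package's choosing) are excluded and counted,
never interpolated. Duplicate timestamps keep the first record. Rows are
sorted by patient then time; changing the RQ grid never changes row
membership or block means.

## Agreement battery

- Bias and SD: mean and sample SD (n−1) of estimate − reference.
- Percentage metrics: no universal definitions exist, so both are explicit
  modes — default "% error" = mean(|Δ|/reference), default "% difference" =
  mean(|Δ|/pair mean), with the Critchley criterion (1.96·SD(Δ)/mean
  reference) selectable.
- Pearson r with 95% Fisher-z CI.
- Concordance: Lin's CCC with n-denominator moments; 95% CI by seeded
  nonparametric percentile bootstrap (2000 resamples) by default, Lin's
  1989 asymptotic variance on the z scale selectable. |CCC| ≤ |r| always
  (fuzz-tested).
- Ratio-band agreement: fraction of pairs with estimate/reference in the
  *closed* intervals [0.85, 1.15] and [0.95, 1.05] (endpoint inclusion is a
  convention choice; ties are measure-zero under the generator).
- Bland–Altman: bias ± 1.96·SD limits of agreement (not t-adjusted; at
  hundreds of pairs the difference is negligible).

All CIs are pooled over measurements and ignore within-patient clustering,
mirroring the pooled design being emulated; clustered or repeated-measures
Bland–Altman corrections are a known limitation, not implemented.

Degenerate inputs: a constant estimate (e.g. the zero formula) has a
well-defined bias and band agreement but no correlation; the summary
reports NaN for r and CCC rather than failing, while the low-level
`pearson_with_ci`/`lin_ccc` raise on zero-variance inputs.

## Calibration

Single-predictor ridge regression of reference REE on VCO₂:
predictor standardized, intercept unpenalized, slope in closed form
β(λ) = Σx̃y / (Σx̃² + λ), λ chosen from a log-spaced grid (1e-4..1e2, 25
points) by 10-fold shuffled cross-validated squared error with the smallest
λ breaking ties. With one predictor the penalty is nearly irrelevant (the
selected λ is typically ≪ n); it is kept because the validated procedure
used it and because it regularizes degenerate resamples.
R² is reported in-sample. The fitted line is rounded half-away-from-zero to
integer coefficients (`REE = intercept + slope·VCO₂`) and the rounded
formula is scored with the full battery. The default source fits on
calorimeter VCO₂ and evaluates on ventilator block VCO₂
(`calibration_source` switches both directions).

`RidgeREECalibrator` follows the scikit-learn estimator contract
(`fit`/`predict`/`get_params`, trailing-underscore fitted attributes) and
composes with sklearn model-selection tools; `fit_ridge()` is the
functional wrapper used by the CLI.

## Numerical and testing choices

- Fold shuffling, bootstraps and the cohort all derive from explicit seeds;
  a `(config, seed)` pair reproduces byte-identical run outputs.
- Test problem sizes: cohort moment recovery uses ~5300 measurements
  (1100 patients), oracle equivalence ~500 measurements, noise tuning
  ~3000, ridge recovery 20 replicates of n = 5000 — sizes at which the
  targeted 2–3 SE bounds are sharp while the whole suite stays fast.
- Statistical recovery checks use cluster-robust standard errors for pooled
  patient-level quantities (repeated measurements share a patient random
  effect; iid CLT bounds would be anti-conservative) and average replicate
  fits when bounding estimator bias, so fixed-seed tests check the
  estimator, not one draw's luck.
- The brute-force oracle tests recompute every performance-table cell with
  plain-Python formulas from the written CSVs; bootstrap CIs are checked
  for bracketing, not equality, since an independent oracle cannot share
  the resampling stream.

## Known limitations

- The pooled CIs ignore clustering (above); between-patient and
  within-patient agreement are not separated.
- The printed "% error"/"% difference" conventions in the emulated setting
  could not be recovered from their values; the modes implemented are the
  defensible candidates.
- The measurements-per-patient family caps at 15; cohorts with extreme
  repeat counts need an explicit `measurement_count_pmf`.
- The block-VCO₂ SD / correlation incompatibility described above is a
  property of the emulated targets, not a tunable of this package.
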