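# Methods

## Models

All predictors share one functional form: log Kp = c + Σ bᵢ·xᵢ, with the
descriptor set distinguishing them.

| model | descriptors | output unit | n (train) |
|---|---|---|---|
| `dermwin_eq1` | log Kow, MW | log10 cm/h | — |
| `zhang_eq2` | E, S, A, B, V, J⁺, J⁻ | log10 cm/s | 274 |
| `ppm_eq5` / `ppm_eq6` | log Kow, log Kaw | log10 cm/s | 175 / 140 |
| `gcgc_eq7` / `gcgc_eq8` | u1, u2 | log10 cm/s | 79 / 64 |

Coefficients are stored exactly as printed in their sources (2–3
significant figures) in versioned JSON files under
`src/skinperm/registry/`; re-deriving extra digits would break
reproducibility of the printed worked values. The convenience wrappers
(`predict_ppm` etc.) evaluate the registry entry through the generic
`predict_linear`, so wrapper and registry agree bit-for-bit by
construction.

Assumptions worth stating explicitly:

* **Neutral species only.** J⁺/J⁻ are identically zero for neutral
  molecules and default to zero *only* for those two fields; every other
  required descriptor that is missing raises an error naming the record
  and descriptor. Ionized species follow different partitioning and are
  out of scope.
* **Units are never converted silently.** The PPM and GC × GC training
  response inherits the unit of the Zhang-model compilation; that
  compilation's unit is recorded as log10 cm/s in the registry metadata
  rather than asserted as fact. Cross-model comparison refuses mismatched
  units; `convert_logkp_unit` applies ±log10(3600).
* **GC × GC scope.** The model is calibrated for nonpolar chemicals; the
  stationary-phase pair it rests on does not encode hydrogen bonding, so
  polar solutes fall outside its applicability domain.

## Descriptor estimation and provenance

Abraham solvation model (ASM) equations estimate partition coefficients
as c + eE + sS + aA + bB + vV (+ lL for gas-phase equations that declare
`l`). The package ships equation files for log Kow and log Kaw as
externally sourced configuration, flagged for verification against the
solvation-chemistry literature; the test suite deliberately exercises
`asm_estimate` with toy coefficient sets only, so its correctness does
not rest on those constants.

When several values of one descriptor coexist (measured, ASM-estimated,
EPI-Suite-estimated), `resolve_descriptor` picks by a configurable
preference order, default experimental > ASM > EPI-Suite — measured data
beat the more accurate estimator, which beats the fragment methods.
Resolution never mutates stored records.

u1/u2 are consumed directly as input columns. The published
orthogonalization from gas–stationary-phase partition coefficients to
u-parameters is not re-derived here; `derive_u_parameters` applies a
user-supplied affine map (2×2 matrix + offset) and errors without one,
rather than guessing the literature transform.

## Calibration statistics

* **RMSE** uses denominator n (not n−p−1) for fit, cross-validated and
  cross-model errors alike, so all three are commensurable; the
  convention is recorded in fit metadata.
* **Q² = 1 − PRESS/TSS** with TSS about the training mean;
  PRESS RMSE = √(PRESS/n). Leave-one-out errors use the hat-matrix
  shortcut eᵢ/(1−hᵢ), which the tests verify equals an explicit n-refit
  loop to 1e−10.
* **Bootstrap SEs** are standard deviations of coefficients over
  case-resampled refits (default 1000); rank-deficient resamples are
  redrawn with a logged count, and persistent deficiency (> half of the
  replicates) aborts with a degenerate-data error.
* **Cross-validation** folds are seeded shuffle-then-chunk; aggregate
  RMSE pools held-out squared errors over all folds and repeats. With a
  single repeat, pooling runs in record order, making k = n reproduce
  leave-one-out bit-for-bit. The bootstrap scheme trains on an n-sized
  resample and tests out-of-bag. A k-nearest-neighbour regression
  baseline is not part of the core battery.
* **Stepwise selection** admits the AIC-minimizing candidate, rejects
  entries whose VIF would exceed the cutoff, then prunes terms with
  coefficient p > p_out or VIF > vif_max (defaults 0.05 and 10, both
  configurable), iterating to a fixed point. A term dropped by backward
  elimination may not re-enter: without that bar, a candidate with
  AIC-worthy but t-test-unworthy support (0.05 < p < ~0.157) cycles in
  and out indefinitely. An empty final model is returned flagged, not
  raised.
* **Comparison R²** is reported both as squared Pearson correlation and
  as the coefficient of determination about the 1:1 line, since the two
  diverge under bias.
* Records with missing values in any modelled column are dropped per fit
  with a logged count — never imputed.

## Influence diagnostics and PCA

Applicability-domain screening reports externally studentized residuals,
leverage (hat values) and Cook's distance with default flags at
|t| > 3, h > 3(p+1)/n and D > 4/n — conventional cutoffs, all
configurable; flagged records are listed for a human decision, never
auto-removed. Exact fits (residual scale numerically zero) studentize to
0/0; they are reported as zero rather than round-off noise.

PCA decomposes the correlation matrix by default (the descriptor columns
have incommensurate scales); covariance PCA is available by flag. Under
correlation PCA, loadings are variable–component correlations, cos2 is
the squared loading (summing to 1 per variable), and eigenvalues sum to
the number of variables. Loading signs are fixed deterministically (the
largest-magnitude loading in each dimension is positive) so results are
stable across linear-algebra backends.

## Synthetic data generator

The generator reproduces the statistical structure of the training
compilations, which is what makes the calibration machinery testable
without the original supplementary tables:

* **PPM conditions** (defaults): n = 175; generating surface
  (−5.41, 0.46, 0.14); residual σ = 0.47 log units;
  corr(log Kow, log Kaw) = 0.09. Marginals log Kow ~ N(2.5, 2.0²) and
  log Kaw ~ N(−3.0, 2.5²) were chosen so the population R² of the
  generating surface is ≈ 0.82 and log Kp spans about seven orders of
  magnitude, matching the compilation's reported spread.
* **GC × GC conditions**: n = 79; surface (−5.35, 0.58, −3.51);
  σ = 0.23; u1 ~ N(4.0, 1.05²), u2 ~ N(0.45, 0.12²), corr = 0.10,
  giving population R² ≈ 0.90.
* **Abraham-descriptor matrix**: 175 × 5 multivariate normal with an
  E/S/B/V block correlated at 0.75–0.85 and A near-orthogonal (0.05),
  placing ≈ 87.6% of the variance in the first two principal components
  — the low effective dimensionality that motivates two-parameter
  modelling.

Correlations are induced exactly in-sample: raw Gaussian scores are
empirically whitened (sample covariance = identity) before coloring, so
every generated dataset carries the exact target correlation and
marginal moments, and only the residual noise varies between seeds.
Optional outlier injection shifts chosen records' response by a
configurable multiple of σ (default +10σ) and records their ids in
`DataFrame.attrs`, enabling end-to-end influence-flagging checks.

What the generator does **not** emulate: real descriptor marginals are
skewed and bounded (V > 0, A mostly zero for non-donors), measurement
error in the descriptors themselves, chemical-family clustering, and any
nonlinearity in the true permeation response. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
stated conditions, not the field accuracy of the published models on new
chemicals.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed (numpy
`default_rng`); CLI pipelines rerun byte-identically. The test suite and
the acceptance script run at the study sizes themselves (n = 175 and
n = 79, 1000 bootstrap replicates, 100 replicate coverage sweeps) —
small enough that the whole battery completes in seconds. The
bootstrap-coverage property is checked per coefficient (nominal 95%
intervals, required ≥ 90/100 replicates each); the joint
all-coefficients event has nominal coverage of only 0.95³ and is not a
meaningful calibration target.

## Known limitations

* ASM coefficient files are configuration, not ground truth; verify
  against the cited literature before production use.
* The u1/u2 derivation path requires the user to supply the published
  transform; no default is provided.
* Stepwise selection with p_out = 0.05 retains a chance-significant
  decoy in roughly a fifth of random datasets — an inherent property of
  the procedure, not a defect; the trace records every add/drop
  decision.
* `correlation_matrix` is O(m²) pairwise loops; adequate for descriptor
  panels, not for thousands of columns.
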