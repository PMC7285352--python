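# Methods

This note documents the models and numerical choices behind the
package, the defaults and why they were chosen, and what the synthetic
benchmark can and cannot show about real data.

## Data model

Spectra are diffuse-reflectance measurements of powdered, freeze-dried
plant material, stored as absorbance log₁₀(1/R) on a uniform wavelength
grid — by default 1100–2000 nm at 2 nm intervals (451 points), the
working range of scanning-monochromator NIR instruments used in forage
analysis. Each sample is measured in triplicate without moving the
probe; the arithmetic mean of the replicates enters all statistics.
Reference values are per-sample constituent concentrations (mg·kg⁻¹ for
alkaloids, mg·g⁻¹ for mycelium) from wet chemistry; they may be missing
for a subset of samples, in which case the sample is excluded from
calibration for that constituent only (reference panels rarely cover
every assay for every sample). Zero-concentration samples are likewise
excluded before calibration: alkaloid-free material carries no signal
for the constituent and only biases the regression.

## Pre-treatments

A treatment code is a scatter letter plus a numeral digit.

Scatter corrections (applied per spectrum, before derivatives):

* **SNV** (`s`): centre to mean 0 and scale to SD 1 (n−1 denominator).
  Removes multiplicative scatter and additive offsets.
* **Detrend** (`d`): residual from a least-squares **degree-2**
  polynomial in wavelength. The degree is the standard choice for
  baseline curvature in powdered samples; the fit uses a [-1, 1]
  rescaled axis for conditioning.
* **SNV + DT** (`m`): SNV first, then detrending of the SNV output.

Derivative numerals (a, b, c, d) = derivative order, gap in grid
points, first and second smoothing segment:

* Segment smoothing is a boxcar mean of width c (valid window only);
  d = 1 means no second smoothing.
* The a-th order gap difference uses spacing b: first order
  x(i+b) − x(i), second order x(i+2b) − 2x(i+b) + x(i).
* Order of operations: smooth(c) → gap difference → smooth(d).
  (0, 0, 1, 1) is the identity. The digit shorthand is
  0 = (0,0,1,1), 1 = (1,4,4,1), 2 = (2,4,4,1), 3 = (2,10,10,1),
  4 = (2,8,6,1).

Edges are truncated to the valid window rather than padded — no data is
fabricated at the spectrum ends — and the wavelength axis is pushed
through the same operators so the truncation stays visible. All
treatments are row-local, hence permutation-equivariant and usable
inside cross-validation without leakage. The scatter-then-derivative
order is the convention of chemometrics packages for scanning NIR; the
stages are exposed separately (`snv`, `detrend`,
`gap_segment_derivative`) so the reverse composition can be built if
ever needed.

## PCA screening and the H statistic

Treated spectra are decomposed by (centred) SVD. Components are
retained up to a cumulative explained-variance target (default 0.99)
with a hard cap of min(n−1, p, 30); an exact k can be requested
instead. Loadings have a deterministic sign convention (the
largest-magnitude element of each loading is positive).

The global H of a spectrum is the squared Mahalanobis distance of its
score vector, each score standardised by that component's training SD
(n−1 denominator), divided by k:

    H(x) = (1/k) Σⱼ (tⱼ / sⱼ)²

Training spectra then average H = (n−1)/n, and the conventional cutoff
H > 3.0 flags spectral outliers. Screening is single-pass: the PCA is
fit once on all samples (outliers included) and not refit after
removal; an iterative variant would change the masked-outlier behaviour
and is deliberately not the default. A consequence worth knowing: a
shape anomaly orthogonal to the retained components is invisible to the
screen, and a variance target of 0.99 retains few components when the
data are low-rank, so screening on raw (`n0`) spectra is the more
sensitive default for gross amplitude/shape corruption.

## Modified PLS

The regression is PLS1 (NIPALS): each factor takes the weight vector
proportional to Xᵀy on the current residuals, scores t = Xw, deflates X
by the score projection and y by its score regression. The
*modification*: after each factor, every X-residual column is divided
by its SD (n−1), and by default the y residual as well; the divisors
are stored per factor and replayed in training order at prediction
time, so prediction is an exact replay of the training pipeline (and an
affine map of the input spectrum — `coefficients()` materialises it).
The rescaling equalises the residual variance across wavelengths
between extractions, damping wavelengths already well modelled.

Properties maintained by construction and enforced in tests:

* scaling off ⇒ exactly classical PLS1 (checked against an independent
  NIPALS implementation to 1e−8 on random instances);
* uniform divisors ⇒ the modification cancels and predictions equal
  PLS1;
* a residual column with zero SD is left unscaled for that factor
  (unit divisor, with a warning) rather than failing the fit.

Whether the y residual should also be standardised is genuinely open in
the field's descriptions of the method; it is on by default and both
settings are exercised in the tests. The default factor count is 10,
the depth routinely used for constituent calibrations of this kind.

## Cross-validation, T outliers and statistics

Cross-validation assigns samples to 6 near-equal groups by a seeded
random permutation; each group is predicted by a model fit on the rest,
and SECV is the root mean square of the pooled held-out residuals
(n denominator). With n groups = n this is exactly leave-one-out.

Chemical outliers are samples whose held-out residual exceeds 2.5 ×
SECV (the T statistic). Removal runs at most twice: flag, drop, re-run
cross-validation with the same seed, flag once more. The statistics
bundle:

* RSQ — squared Pearson correlation of reference and prediction;
* SEC — √(SSE/(n − k − 1)) in the calibration context (degrees of
  freedom corrected for the k factors and intercept);
* SEP = RMSE — √(SSE/n) in validation contexts;
* SEPc — √(Σ(residual − BIAS)²/(n−1));
* BIAS — mean(reference − prediction);
* RPD — reference SD divided by SEP by default; an SD/SECV variant is
  available and the denominator used is recorded in the object. The
  SD/SEP default is the form consistent with the published summary
  ratios this package anchors against (e.g. 1008/310 = 3.252);
  RPD > 2.0 is the usual threshold for a usable calibration;
* a two-sided paired Student's t-test on (reference, prediction), with
  p = 1 by convention for identical vectors.

These obey the exact identity SEPc²(n−1) + n·BIAS² = n·SEP², which the
tests assert instead of any rounded published values.

## Grid search

For one constituent, the search crosses 20 treatment codes at the
screening stage with 20 at the regression stage (400 cells). Per
screening code: treat, fit PCA, drop H > 3.0 samples. Per regression
code: treat the *raw averaged* spectra of the survivors with the
regression-stage code, cross-validate, run two-round T removal, refit
on the survivors and collect statistics. Treatments being row-local,
each of the 20 treated matrices is computed once and rows are subset
per cell, which makes sequential and any concurrent evaluation
byte-identical. Cell failures (e.g. too few samples for the factor
count) are recorded in the cell and never abort the grid.

Selection is lexicographic — smallest SECV, then largest calibration
RSQ, then largest internal-validation RPD, then grid order — because
SECV is the one criterion that measures out-of-sample accuracy; the
rule is recorded in the report. Internal validation here means
predicting the final calibration samples with the final model; the
external 25 % split (seeded, round(0.75·n) calibration samples) is
held out entirely.

## Synthetic data generator

The generator emulates the statistical structure of a heterogeneous
field collection of endophyte-infected meadow fescue:

* **Concentrations.** Total lolines are log-uniform over
  101–5629 mg·kg⁻¹ (log-uniform reproduces the wide right-skewed ranges
  of field surveys better than uniform). Shares of NAL/NANL/NFL are
  Dirichlet with mean (0.11, 0.16, 0.73) and precision 300, so NFL
  averages 73 % of the total. Mycelium is log-uniform over
  0.22–3.97 mg·g⁻¹ and coupled to total lolines through a Gaussian
  copula with latent correlation ρ = sin(πτ/2) targeting Kendall
  τ = 0.48 — a rank-based coupling because the association in real
  material is monotone, not linear.
* **Spectra.** A smooth dry-plant baseline (quadratic in the scaled
  axis, 0.45 + 0.12x + 0.06x², plus broad water bands at 1450 and
  1940 nm) plus per-constituent Gaussian absorption bands scaled by
  concentration (Beer–Lambert mixing). Band positions/widths/amplitudes
  are configuration, not constants; defaults put each constituent's
  bands at distinct C–H/N–H overtone-like positions with peak analyte
  contributions of ~0.15–0.35 AU.
* **Artifacts.** Per-sample multiplicative scatter (lognormal,
  σ = 0.15 — particle-size scatter dominates powdered-plant
  reflectance, and at this level scatter-corrected models reliably beat
  raw-spectrum models, which is the structural point of the scatter
  family), additive offset (SD 0.05 AU), linear tilt (SD 0.02 AU across
  the half-span), and white per-replicate noise (SD 3×10⁻⁴ AU, typical
  scan-averaged instrument noise). Replicates (3 per sample) share the
  analyte signal and scatter, differing only in noise.
* **References.** Reported values get multiplicative noise with CV 3 %
  (a realistic assay repeatability); the reported total is the sum of
  the three reported lolines, as it would be when the total is a
  derived quantity.
* **Injected outliers** for screening tests: spectral outliers get a
  5–10× amplitude blow-up, a 6–12 nm wavelength shift and a spurious
  narrow band scaled to the spectrum's own SD (pure amplitude scaling
  alone would be removed by SNV and prove nothing about shape
  screening); chemical outliers get all reference values displaced by
  6 column SDs.

The generator is a pure function of its configuration (seed included).

### What the benchmark does and does not show

Passing the synthetic suite demonstrates that the machinery is correct:
the algebraic identities hold, the PLS1 reduction matches an
independent implementation, screening flags the corruption it is
designed to flag, and the full grid recovers a constituent generated by
a linear mixing model with high fidelity (cross-validated RSQ > 0.99,
RPD ≫ 2 — far better than any real calibration, because the synthetic
world is linear with a 3 % reference-noise floor and no
constituent-correlated interferents). It does *not* show that real
loline calibrations will reach any particular RSQ/SECV: real spectra
have correlated biochemical backgrounds, moisture/particle-size
interactions, nonlinear detector effects and reference-method biases
that the generator deliberately omits. Field-scale performance figures
can only come from field data.

## Problem sizes and numerical notes

* Default study-like conditions: 190 samples × 3 replicates, 451-point
  grid; the full 400-cell grid on the 75 % calibration split runs in
  well under a minute on one CPU. Screening-power checks use 120
  samples per seed across 10 seeds.
* SD computations use the n−1 denominator throughout (SNV, H scores,
  MPLS residual scaling, reference SD) for internal consistency.
* Degenerate inputs fail loudly with typed exceptions: constant
  spectra under SNV, zero-variance references, windows exceeding the
  grid, more factors/components than the data rank supports, group
  counts exceeding n, all-samples-removed outlier elimination.
* Ties in the PCA sign convention (a zero maximal loading element) and
  in best-equation selection resolve deterministically (positive sign;
  grid order).
* Float round-tripping: datasets are written with shortest round-trip
  reprs and read with round-trip parsing, so write→read is bit-exact.

## Known limitations

* The MPLS residual-standardisation variant follows the
  Shenk–Westerhaus description (divide X and y residuals by their SDs
  between factors, replay divisors at prediction); proprietary
  implementations may differ in unpublished details, so agreement with
  any specific commercial software is not guaranteed beyond the
  documented properties.
* Single-pass H screening can mask shape anomalies outside the
  retained subspace (see above).
* No wavelength interpolation between instruments, no JCAMP-DX/SPC
  binary formats, no MSC/OSC/wavelet pre-treatments, no PLS2.
* The number of factors is fixed per fit (default 10); per-cell factor
  search is not part of the grid.
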