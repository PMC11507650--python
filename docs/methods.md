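# Methods

`crabspec` implements a complete near-infrared (NIR) diffuse-reflectance
origin-authentication workflow for shell samples of three geographic
origin classes, together with a synthetic-data generator that makes every
stage testable without access to real spectra. This note records the
models, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## The data model

Spectra live on a uniform descending wavenumber grid; the emulated
FT-NIR instrument scans 10,000 → 3800 cm⁻¹ at 2 cm⁻¹ resolution (3101
points). A sample's spectrum is modeled as

    x(ν) = m · [ base(ν) + Σ_b A_b · φ_b(ν) ] + a + ε(ν)

* `base(ν)` — a class-independent background: a gentle absorbance ramp
  (0.40–0.60 AU across the scan) plus three broad Gaussian absorption
  peaks (σ = 150 cm⁻¹) near 5100/7000/8500 cm⁻¹ for abdomen spectra and
  5200/6900/8400 cm⁻¹ for carapace spectra, with amplitudes
  0.50/0.35/0.30 AU. These mimic the O–H/C–H/N–H overtone and
  combination bands that dominate biological NIR spectra.
* `φ_b(ν)` — two class-discriminative band profiles, raised-cosine
  (cos²) bumps supported exactly on 10,000–9500 and 9000–8500 cm⁻¹ and
  identically zero outside. Compact support makes the "signal only in
  the planted bands" invariant exact rather than approximate.
* `A_b` — per-class additive amplitudes on the two bands (see
  calibration below).
* `m ~ N(1, scatter_sd)`, `a ~ N(0, baseline_sd)` — a per-sample affine
  scatter distortion (default scatter_sd = 0.05, baseline_sd = 0.02 AU).
  This is exactly the model that multiplicative scatter correction (MSC)
  inverts, so MSC correctness is testable by construction.
* `ε` — white noise with sd `noise_sd` per replicate scan. Three
  replicate scans per sample are averaged, which divides the noise
  variance by 3. The default `noise_sd = 0.10` AU is interpreted as the
  total within-origin spectral variability (dominated by
  sample-to-sample biological variation rather than detector noise);
  treating it as white is a simplification — real biological variation
  is spectrally smooth, so Savitzky–Golay smoothing removes more of our
  noise than it would of real within-class variation.

### Calibration of the class separation

The two band profiles have disjoint support and are therefore orthogonal
directions in spectrum space, so the three class means can be placed
exactly in a 2-D plane. The generator puts them at the vertices of an
equilateral triangle (equal pairwise difficulty) and solves for the
circumradius such that the ideal (Bayes) accuracy of the noise-only
model equals a target, 0.95 by default. For three equidistant Gaussian
classes the per-class correct probability is a bivariate-normal orthant
probability with correlation cos 60° = ½ at threshold d/(2σ), where d is
the pairwise mean distance and σ = noise_sd/√n_replicates; the radius is
found by `brentq` on that exact expression. A Monte-Carlo nearest-mean
check in the test suite confirms the empirical ideal accuracy lands
within ±0.02 of the target. This calibration is scale-free: only d/σ is
fixed, and the absolute absorbance scale stays in a realistic range.

## Pretreatments

* **MSC** — ordinary least squares of each spectrum on a reference
  (the column-wise mean of the *training* rows only; fitting the
  reference on all rows would leak test information, and the pipeline
  exposes `fit_on="all"` only for strict-replication comparisons).
  Output `(x − â)/b̂`. Slopes |b̂| < 1e−12 raise with the offending row
  indices.
* **SNV** — per-row standardization to mean 0, sd 1 using the sample
  (n−1) standard-deviation convention (so `[1,2,3] → [−1,0,1]` exactly).
  Constant rows raise and name the offending sample id.
* **SG smoothing** — `scipy.signal.savgol_filter` with mirror padding;
  defaults window 15, polyorder 3, 0th derivative. SG reproduces
  polynomials up to the fit order exactly in the interior; derivatives
  are deliberately out of scope.

## SPXY partitioning

Pairwise Euclidean distances are computed separately in spectrum space
and label space (labels one-hot encoded: 0 within class, √2 across —
the minimal embedding of categorical origins into the joint-distance
framework), each normalized by its maximum, and summed. Selection is
greedy maximin starting from the most distant pair; ties break toward
the lowest index so splits are exactly reproducible. The implementation
is validated against a brute-force loop oracle on all instances with
n ≤ 8.

## PLS core

Single-response, mean-centered NIPALS (no autoscaling — the absorbance
columns share units). For a univariate response each component is
closed-form: w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt. The regression vector b is
assembled through the recurrence r_k = w_k − Σ_{j<k}(p_jᵀw_k) r_j, so
ŷ = ȳ + (x − x̄)ᵀb reproduces the NIPALS fitted values to 1e−8, and with
full components b equals the least-squares solution. Class labels enter
as integer codes 0/1/2 in the declared class order; a single coefficient
vector is what the three selectors consume. (With the equilateral class
geometry an affine map from the 2-D signal plane to any assignment of
the three codes exists, so no coding choice hides the planted signal.)

RMSECV uses k-fold cross-validation with a *canonical* fold assignment:
rows are ranked by a lexicographic sort on (y, X) before the seeded
permutation that deals out folds, so the result is independent of input
row order. Within one selector run the fold assignment is computed once
and shared across all candidate variable subsets, so subset comparisons
are not confounded by fold noise.

## Wavelength selectors

All three selectors are deterministic given (data, parameters, seed).

* **CARS** (100 Monte-Carlo runs, 5-fold CV by default). Per run: fit
  PLS on 80% of the training samples over the surviving variables; keep
  the top ⌈r_i·p⌉ variables by |b| where r_i = a·e^(−k·i) with a, k
  solved from r_1 = 1 and r_N = 2/p (exponential decay schedule); then
  adaptive reweighted sampling — p draws with replacement with
  probability ∝ |b|, deduplicated. The number of latent variables is
  chosen once by RMSECV on the full variable set and reused for the
  Monte-Carlo weighting fits; letting every weighting fit use up to 10
  components lets |b| soak up noise directions and visibly degrades
  band recovery. The subset at the global RMSECV minimum is returned.
* **BOSS** (1000 bootstrap subsets/iteration, best 10% of sub-models by
  RMSECV, per-subset component cap 5). Weights update proportionally to
  the summed |b| over the elite sub-models, plus a geometrically
  decaying share (1e−4) of the previous weights: variables missing from
  every elite model are softly shrunk rather than zeroed, and only stop
  being drawn once their weight decays below a relative floor (1e−6 of
  the maximum). The bootstrap draw count follows the active variable
  set; with a draw count pinned at the original p the elite support
  stops shrinking once every subset contains the whole support, and the
  iteration stalls — the shrinking draw count restores the
  shrink-to-one dynamic the method is defined by. Iterations cap at 100.
* **UVE**. As many artificial noise variables as real ones (uniform
  [0,1] × 1e−10: numerically inert, yet with well-defined coefficients)
  are appended; coefficient vectors are collected per left-out fold over
  8 repeats of the 5-fold scheme (40 vectors). With a single 5-fold pass
  the stability t = mean/sd has 4 degrees of freedom and the cutoff —
  the largest |stability| among noise variables, i.e. the symmetric
  threshold pair — becomes so heavy-tailed that essentially no real
  variable survives; repeats make the cutoff meaningful. Real variables
  whose |stability| exceeds the cutoff survive. On pure noise, the
  expected survivor fraction is ≈ 1/(p+1) (~0.3%); if nothing survives,
  the single most stable real variable is returned with a
  `fallback_used` flag so downstream stages always get a non-empty set.

Band recovery is quantified by a hypergeometric tail test of the overlap
between the selected set and the planted-band grid positions.

## Classifiers

* **SVM** — RBF kernel, C = 1.0, γ = 0.5 by default, one-vs-one
  multiclass (scikit-learn `SVC`). No feature scaling beyond the chosen
  pretreatment.
* **BP** — feed-forward net input → 6 → 3 → K (softmax), cross-entropy,
  SGD (`MLPClassifier`), learning rate 0.003, up to 2500 iterations,
  stopping when the loss stops improving by more than 5e−6
  ("stopping error"). Seeded initialization makes retraining
  bit-identical.
* **1-D CNN** — Conv(8 kernels, k=3, ReLU) → Conv(16, k=3, ReLU) →
  MaxPool(2) → Dense(6, ReLU) → Dense(K, softmax); Adam at initial
  learning rate 1e−4, batch 4, 299 epochs by default. Implemented in
  numpy (im2col convolutions, analytic backprop verified against
  numerical gradients to 1e−4 relative). No padding, stride 1: an input
  of 29 selected wavelengths flows 29 → 27 → 25 → 12 → 192 → 6 → 3.
  Inputs need ≥ 8 points for the shape chain to stay positive.
* **Grid search** — exhaustive Cartesian product, stratified k-fold CV
  accuracy on the training set, ties to the earlier combination.

## Pipeline

Stage order: generate/load → (optional per-class subsampling) → SPXY
split on raw spectra → pretreatment (fit on train) → selection (on
train) → train → evaluate. The split precedes pretreatment so that the
MSC reference and the selected wavelengths never see test rows; a
refit-comparison test asserts this. One seed drives every stage, and two
runs of the same configuration produce byte-identical JSON reports
(timings aside). The dataset-size ablation subsamples each class without
replacement (seeded, sorted so a full-size "subsample" is the identity)
and reruns the pipeline per size.

## Metrics

Per-class precision, recall and F1 are one-vs-rest; the headline
accuracy is trace/total of the K×K confusion matrix (the only reading
that yields one accuracy per model when K > 2; the per-class binary
accuracies relate to it by mean = (K−2)/K + 2·acc/K). Zero-denominator
metrics report 0 with an `undefined` flag instead of NaN so reports
serialize cleanly. Percentages are rounded to two decimals only at
presentation.

## Problem sizes and benchmark scope

The simulation study in the tests and in `scripts/acceptance.py` uses
the full sample design (130 samples per origin, 310/80 SPXY split) on a
20 cm⁻¹ grid (311 points) — coarse enough that the complete factorial,
including BOSS's ~10⁵ bootstrap sub-models, runs on a laptop in minutes,
while keeping the p ≈ n regime that makes variable selection
non-trivial. BOSS's inner k-fold PLS evaluation is compiled with numba;
a unit test pins it to the reference implementation.

Under these conditions (ideal accuracy calibrated to 0.95) the
MSC → CARS → SVM pipeline averages ≈ 92% test accuracy over five seeds,
all three selectors recover the planted bands with hypergeometric
p < 1e−10, and accuracy decreases on average as the dataset shrinks from
130 to 100 to 80 samples per class — though individual seeds fluctuate
by several points, so the ablation's monotonicity is a statement about
means.

## What passing does and does not show

The generator plants exactly the structure the methods assume: affine
scatter (MSC's model), band-limited class signal (the selectors'
target), Gaussian noise. Passing therefore demonstrates internal
correctness and qualitative agreement with the published behavior of
these methods — not that the pipeline would reach any particular
accuracy on real shell spectra, whose within-class variability is
structured, whose discriminative bands are neither compact nor known,
and whose scatter is only approximately affine. The real-data headline
numbers quoted in the README are reproduced only at the level of their
metric arithmetic (P/R → F1), since the underlying spectra are not
public.

## Known limitations

* White within-class noise (see above) flatters SG smoothing.
* Single-response PLS with integer class codes is the field's common
  shortcut for selector scoring, not a principled multiclass model.
* BOSS's iteration cap (100) can stop short of the literal
  one-variable endpoint; the RMSECV minimum invariably occurs far
  earlier, so the returned set is unaffected.
* The CNN and BP models are small and CPU-bound by design; no GPU path.
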