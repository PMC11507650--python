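# crabspec

Chemometrics toolkit for **NIR diffuse-reflectance origin
authentication**: can a fast, non-destructive near-infrared scan tell
where a food product came from? The motivating application is the
Chinese mitten crab market, where premium lake-of-origin labels are
widely counterfeited and existing assays (isotope ratios, mineral
fingerprints, chromatography) are slow and destructive. The package is
aimed at chemometricians and food-authentication researchers who want a
tested, reproducible implementation of the full workflow:

1. **Synthetic spectra** with planted, band-limited origin signal — the
   statistical structure of three-origin shell spectra (broad
   absorption peaks, multiplicative scatter, replicate averaging) so
   every downstream stage is testable without proprietary data;
2. **Pretreatments** — multiplicative scatter correction (MSC),
   standard normal variate (SNV), Savitzky–Golay smoothing;
3. **SPXY partitioning** — Kennard–Stone-style maximin sample selection
   on a joint spectrum+label distance;
4. **Wavelength selection** — CARS (competitive adaptive reweighted
   sampling), BOSS (bootstrap soft shrinkage) and UVE (uninformative
   variable elimination), all built on a shared NIPALS PLS1 core scored
   by RMSECV;
5. **Classification** — RBF-kernel SVM, a small backpropagation network
   (input→6→3→K) and a 1-D CNN (Conv8·k3 → Conv16·k3 → MaxPool2 →
   Dense6 → softmax), evaluated with one-vs-rest precision/recall/F1
   and multiclass accuracy.

## The core statistics

For spectra X (n × p, absorbance on a 10,000→3800 cm⁻¹ grid at 2 cm⁻¹,
p = 3101) and class codes y, the selectors rank wavelengths through the
PLS regression vector **b** (ŷ = ȳ + (x − x̄)ᵀb) and keep the subset S
minimizing

    RMSECV(S) = √( Σᵢ (yᵢ − ŷ₋ᵢ(S))² / n ),

the k-fold cross-validated error. CARS shrinks S along an exponential
decay schedule r_i = a·e^(−k·i) (r₁ = 1, r_N = 2/p) with resampling
∝ |b|; BOSS reweights variables by their summed |b| over the best 10%
of bootstrap sub-models (soft shrinkage); UVE keeps variables whose
coefficient stability mean/sd beats every appended noise variable.
Classification quality is reported per class one-vs-rest:

    P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R),  Acc = trace/total.

## Worked example

`examples/05_full_pipeline.py` generates the synthetic three-origin
study (130 samples per lake, calibrated so the ideal classifier would
reach 95% accuracy), splits 310/80 with SPXY, applies MSC fit on the
training rows, selects wavelengths with CARS and classifies with the
SVM (C = 1.0, γ = 0.5, RBF):

```
selected wavelengths: 47 (best CARS iteration 11)
test accuracy: 96.25%
   class    n      P%      R%     F1%
      WL   29   93.55  100.00   96.67
      TL   25  100.00   96.00   97.96
      HL   26   96.00   92.31   94.12
confusion matrix (rows true WL/TL/HL, cols predicted):
[[29, 0, 0], [0, 24, 1], [2, 0, 24]]
```

WL/TL/HL are the three origin classes (Weishan, Tuo and Hongze lakes).
With an 80-sample test set the accuracy fluctuates a few points around
the 95% ideal ceiling (≈ 92% averaged over seeds). The other examples
show the generator (`01`), scatter correction inverting the affine
distortion to machine precision (`02`), the SPXY split (`03`),
planted-band recovery by CARS/UVE with hypergeometric enrichment
p < 1e−12 (`04`) and the dataset-size ablation (`06`). A thin CLI wraps
the same pipeline: `crabspec simulate`, `crabspec run`, `crabspec
ablate` (see `crabspec --help`).

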