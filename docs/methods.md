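# Methods

`lnradiomics` replicates, end to end, a single-slice CT radiomics analysis
for preoperative lymph-node (LN) metastasis assessment in colon cancer:
146 texture features per node, LASSO feature selection, kernel-SVM
classification, and a statistically rigorous comparison against the
clinical size rule (long-axis diameter > 10 mm ⇒ metastatic). Because no
patient images are publicly deposited, the pipeline runs on synthetic
cohorts whose statistical structure matches what the analysis assumes; the
synthetic generator is first-class, tested code.

## Synthetic cohorts

Each case is one LN on one 2-D slice at 1 mm isotropic in-plane spacing
(the analysis slice of maximal diameter; all computation is 2-D).

**Size law.** The long-axis diameter is drawn from a normal distribution
truncated below at 4 mm (no non-physical diameters). The underlying
location/scale are solved numerically so the *truncated* law has exactly
the reported class moments — normal 12.12 ± 5.74 mm, metastatic
17.37 ± 8.48 mm — since naive truncation would inflate the mean by
≈ 0.9 mm and shrink the SD. The short axis is `ratio × long` with
`ratio ~ U(0.55, 0.9)` for both classes, floored at 3 mm (nodes thinner
than ~3 px cannot support neighbourhood texture operators; the smallest
reported node areas are ≈ 10 mm²). The mask is an ellipse with uniform
random orientation.

**Texture.** Interior intensity = base level (60, arbitrary units)
+ stationary Gaussian random field + white noise (SD 2). The field has a
squared-exponential correlation function — realized as Gaussian smoothing
of white noise, rescaled by the exact discrete filter norm to unit marginal
variance — with correlation length 2.0 mm in both classes and marginal SD
5.0 (normal) vs 6.5 (metastatic): metastatic nodes are more heterogeneous.
No LN interior intensity statistics are reported anywhere, so these
amplitudes are free parameters; they were fixed once so that the radiomic
model's separability on default cohorts lands in the same range as the
published model AUCs (test ≈ 0.83–0.89 vs published 0.825) instead of
saturating near 1, which would make every downstream comparison trivial.

**Demographics.** Age ~ N(62.5, 12.8²) clipped to [25, 95]; gender
(52% M), tumor location (47% left) and histological grade (66% well) are
drawn independently of the class label. Only node size and texture carry
class signal: the pathology-linked covariates (perineural/vessel invasion,
T-stage) that differ by class in the real cohort never enter any model and
are not emulated. A consequence worth knowing: in the default cohort *both*
axes carry (correlated) size signal, so the exhaustive demographic search
may return `{long_axis}` or `{short_axis, long_axis}` depending on CV
noise; the "short axis wins alone" behaviour is exercised on cohorts where
only the short axis is class-informative.

**What passing tests do not show.** The generator produces clean elliptical
masks, stationary Gaussian texture and an exactly specified acquisition
model. Real CT adds Hounsfield calibration, partial-volume and segmentation
variability, non-stationary internal architecture (fatty hilum, necrosis)
and inter-scanner effects; a pipeline that passes here is *mechanically*
correct, not clinically validated.

## Preprocessing

Slices are resampled to 1 mm in-plane with cubic b-splines
(`scipy.ndimage.zoom`, mirror boundary, grid mode); masks use
nearest-neighbour resampling with a 0.5 threshold. The analysis slice is
the one whose mask has the largest maximal Feret diameter (ties → lowest
index). Intensities are min-max normalized over **in-mask pixels only**
(configurable to whole-slice bounds; per-ROI was chosen so gray levels
describe the node, not surrounding fat/bowel) and quantized to B = 8
levels: `level = floor(v·B) + 1`, v = 1 → B, flat region → all level 1.
Quantization is monotone and invariant to positive affine intensity maps.

## The 146-feature panel

| Block | Index | Features |
|---|---|---|
| FoS | 1–6 | mean, variance, skewness, kurtosis, energy (Σp²), entropy (bits) of the level histogram |
| GLCM | 7–12 | energy, contrast, correlation, homogeneity, entropy, dissimilarity — symmetric normalized matrices, distance 1 px, averaged over 0°/45°/90°/135° |
| GLRLM | 13–19 | SRE, LRE, GLN, RP, RLN, LGLRE, HGLRE — mask-truncated maximal runs, direction-averaged; RP = runs / in-mask pixels |
| LBP | 20–29 | riu2 histogram, P = 8, R = 1 (codes 0–8 + non-uniform), on the continuous normalized image, interior pixels only |
| Fractal | 30 | box-counting dimension of the supra-median set, dyadic boxes up to half the bounding box |
| Wavelet | 31–118 | per db2 subband (LL, LH, HL, HH order): FoS(6) + GLCM(6) + GLRLM(7) on the re-normalized, re-quantized subband + relative energy, log-energy (log1p, finite for zero subbands), mean |coeff| = 22 × 4 |
| Gradient | 119–137 | FoS + GLCM + GLRLM of the Sobel magnitude inside the 1-px-eroded mask |
| Shape | 138–146 | area, perimeter, major/minor axis, eccentricity, solidity, extent, equivalent diameter, circularity |

Degenerate-input conventions (all chosen so every feature stays finite):
skewness/kurtosis of a zero-variance histogram are 0; GLCM correlation of a
single-level matrix is 1; a flat ROI's supra-median set is empty and the
fractal dimension is 0 with a warning; directions with no in-mask pixel
pair are excluded from direction averages; for the smallest nodes whose
eroded interior holds no pixel pair, the gradient-domain substrate falls
back to the full mask. Wavelet and gradient images are re-quantized
independently of the intensity image because their dynamic ranges differ.

The within-block order of the GLCM (energy first, contrast second) and
GLRLM (RP fourth) panels pins the landmark features at their published
indices: F⁸ = intensity GLCM contrast, F¹⁶ = run percentage,
F¹²⁶/F¹²⁹ = contrast/entropy of the gradient image. The source tables
never name the remaining features; the standard Haralick/Galloway panels
above are the reconstruction, and the wavelet block places LL first, so
"low gray level run emphasis of the approximate wavelet image" is
addressed by alias (canonical index 48) rather than a printed index. The
spec of the panel — 88 wavelet features against 4 × 19 = 76 from the three
stated families — is completed with the three per-subband summaries; the
registry (`feature_registry()`) documents every index, domain, family and
alias machine-readably.

**Perimeter estimator.** Staircase-counting perimeters (Crofton, weighted
pixel counts) overestimate smooth digital boundaries by 4–8% at these
resolutions, which biases circularity visibly (a radius-10 disk would score
≈ 0.94). The perimeter is therefore the length of the 0.5 iso-contour of
the mask smoothed with a σ = 1 px Gaussian, which is close to unbiased for
smooth blobs like LNs (disk circularity 1.00 ± 0.01); degenerate masks fall
back to Crofton.

## Models and selection

* **Clinical rule**: metastatic iff long axis > 10 mm (strict).
* **Demographic SVM**: exhaustive enumeration of all 63 non-empty subsets
  of {age, gender, grade, location, short axis, long axis} (binary
  covariates 0/1-coded); each subset scored by stratified 10-fold CV error
  of an RBF SVM; ties → smaller subset, then lexicographic order.
* **Radiomic SVM**: LASSO regression of the 0/1 label (squared-error loss,
  matching a cross-validation *MSE* curve; logistic loss would be the
  alternative) over a 100-point geometric λ grid from λ_max down by 10⁻³,
  features standardized per training fold; λ* minimizes the mean 10-fold
  CV MSE (`lambda_rule="1se"` is available and sparser). The nonzero-weight
  features feed an RBF SVM whose (C, γ) come from a grid search
  (C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1, 1}) under the same
  stratified folds, refit on the full training set. On the synthetic
  cohorts' strongly correlated panel the CV-MSE minimum typically keeps
  15–30 features — sparser rules exist, but the minimum-MSE rule is the
  protocol replicated here.

The cohort is split 80/20 with per-class `round(n·0.8)` sampling, so a
390-case cohort reproduces the published 312 (157 + 155) / 78 (39 + 39)
composition. No statistic of the test cohort reaches any fitted parameter;
standardization happens inside the CV pipeline.

If the LASSO selects nothing (possible under a pure-noise cohort), the
radiomic model falls back to the first feature entering the regularization
path, so the pipeline always produces a model; the event is visible in the
run report (`selected_features` empty, `used_features` length 1).

## Evaluation

Accuracy, sensitivity and specificity are reported in % to 2 decimals.
`counts_from_rates` inverts printed rates to integer confusion counts with
half-away-from-zero rounding; the round trip reproduces every printed
count/rate pair of the source performance table (204, 49, 210, 57, 253,
62, 315 correct classifications). The AUC is the Mann–Whitney statistic
(ties ½) with the DeLong structural-components variance; the default 95%
CI is the symmetric normal approximation on the AUC scale, clipped to
[0, 1] (matching the symmetric "AUC ± CI" presentation; a logit-scale CI
with better boundary behaviour is available via `ci_scale="logit"` —
measured coverage at n = 40 + 40, true AUC 0.8: ≈ 93.5% AUC-scale, ≈ 95%
logit-scale). Model pairs are compared with the paired DeLong z-test; a
zero-variance difference (identical scores) reports p = 1 with a
degeneracy flag. Cohort tables use Wilcoxon rank-sum for numeric and a
binomial test (metastatic-class proportion against the normal-class
proportion) for categorical variables; no multiplicity correction is
applied, mirroring the original analysis. The diameter-histogram overlap
statistic uses fixed-width bins anchored at the pooled minimum (the
anchoring is a convention; none is stated in the source).

## Problem sizes and determinism

Default study cohorts are 196 + 194 cases (312 train / 78 test). One full
replicate — generation, 390 × 146 feature extraction, LASSO, both SVMs,
evaluation — takes roughly 10 s on one core; the repeated-ranking analyses
in the test suite and acceptance script use 100 and 20 replicates
respectively, and the DeLong coverage simulation uses 1000 datasets of
n = 80. Every random draw flows from explicit integer seeds (cohort, split
and CV seeds are separate and recorded in the run manifest); re-running
with the same manifest reproduces all metric JSON byte-for-byte.

## Known limitations

Single 2-D slice per node; no 3-D texture, size-zone or dependence
matrices; no IBSI naming compliance; no probability calibration or
decision-curve analysis; no survival endpoints. The demographic search is
exhaustive only because the candidate set is six variables. The synthetic
cohorts validate machinery and protocol, not clinical performance.
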