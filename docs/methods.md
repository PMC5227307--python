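# Methods

`busfusion` classifies breast tumors in B-mode ultrasound (BUS) images as
benign or malignant from two complementary views of the manually outlined
tumor — local gray-level texture and global shape — and fuses the two
probabilistically. This note records the model, its parameters, the
numerical conventions, and the design choices that were genuinely open.

## Classification model

**Multiple-ROI texture arm.** The tumor is divided into uniform,
nonoverlapping square regions of interest (ROIs). From each ROI, sixteen
gray-level co-occurrence matrices (GLCMs) are accumulated — distances
d ∈ {1, 2, 3, 4} pixels crossed with orientations θ ∈ {0°, 45°, 90°, 135°} —
and twenty scalar statistics TF1–TF20 (autocorrelation, contrast,
correlation, cluster prominence/shade, dissimilarity, energy, entropy,
homogeneity, maximum probability, sum-of-squares variance, sum
average/entropy/variance, difference variance/entropy, the two information
measures of correlation, and the two normalized inverse-difference forms)
are computed per GLCM, giving a 320-dimensional vector per ROI. Each ROI is
classified by an RBF-kernel support vector machine
(k(x, x′) = exp(−‖x−x′‖²/2σ²)) whose margins are mapped to posterior
probabilities with Platt's sigmoid. The tumor is called malignant iff
strictly more than 50% of its ROIs are classified malignant (an exact tie is
benign), and its posterior likelihood is the mean posterior of the ROIs that
agree with the winning class.

**Morphology arm.** Eighteen whole-tumor descriptors MF1–MF18: area,
perimeter, form factor 4πA/P², roundness 4A/(π·maxdiam²), aspect ratio,
convexity, solidity, extent, undulation count, compactness P²/A (MF1–MF10);
major/minor axis lengths, their ratio, perimeter ratio, overlap fraction and
orientation of the moment-matched best-fit ellipse (MF11–MF16); and the
entropy and variance of the normalized radial length (NRL) of the boundary
(MF17–MF18). A second Platt-calibrated RBF-SVM classifies this vector.

**Decision fusion.** Writing d₁, d₂ for the two arms' posterior malignant
likelihoods of a tumor, the fused decision is the Gaussian Naive-Bayes rule
ŷ = argmax_y P(y)·∏ᵢ P(dᵢ|y) with per-class univariate Gaussian
class-conditionals estimated by maximum likelihood on training tumors
(priors = class frequencies; variances floored at 1e−6). The factorized
form follows from the conditional-independence assumption between the two
arms; a full per-class 2×2-covariance variant is available
(`fusion_variant: full`) for comparison but is not the default. Scores are
evaluated in the log domain, so extreme inputs cannot underflow; exact ties
go to benign.

**Baselines.** Three conventional arms are always evaluated alongside:
texture of the single minimum-bounding-rectangle ROI, morphology alone, and
their concatenation (338 features).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `target_spacing_mm` | 0.1 | canonical isotropic pixel size; all cases are resampled to it |
| `glcm_levels` (G) | 32 | gray levels after uniform quantization; keeps a 10×10-px ROI's GLCM from being pathologically sparse while retaining contrast resolution |
| `glcm_symmetric` | true | symmetric accumulation; Haralick's marginal-based features assume it |
| `roi_side_mm` | 1.0 | 10×10 px at 0.1 mm; small enough to isolate local texture, large enough to estimate second-order statistics |
| `min_inside_fraction` | 1.0 | tiles must lie fully inside the tumor, so no surrounding tissue enters the texture analysis; configurable for sensitivity analyses |
| `selection_bins` | 10 | equal-frequency bins for mutual information |
| `top_l_max` | 15 | deepest top-l group evaluated during incremental selection |
| `selection_sigma`, `selection_C` | 5, 10 | fixed mid-range SVM used as the selection evaluator before tuning (selection and tuning alternate once: select → tune, not iterated) |
| grid | integers 2–99, step `grid_step` | exhaustive (σ, C) search maximizing mean CV accuracy; ties → smallest C, then smallest σ |
| `platt_folds` | 3 | internal folds producing out-of-fit margins for the sigmoid fit |
| `max_train_rois_per_tumor` | 8 | per-tumor cap on training tiles (see problem sizes); testing always votes over *all* tiles |
| `undulation_threshold_mm` | 0.3 | minimum hull-to-boundary excursion counted as a concavity segment |
| `nrl_bins` | 10 | NRL histogram bins for MF17 |
| `cv_folds` | 5 | tumor-level stratified cross-validation |

## Numerical conventions

* Gray levels are 0-based; logarithms are natural; 0·log 0 ≡ 0 throughout.
* GLCM orientation uses the Haralick/Chebyshev convention: distance d at 45°
  is the offset (−d, +d), not a rounded Euclidean step. On a constant patch
  the features take their limits (energy 1, entropy 0, correlation 1,
  information measures 0). TF15 is the variance of the difference histogram
  p_{x−y} (one of two variants in the literature).
* The perimeter is the polygonal length of the traced 8-connected boundary
  chain (diagonal steps √2), used consistently in MF2, MF3, MF6, MF10 and
  MF14. This digital chain overestimates smooth contours by ≈5%, so the
  form factor of a rasterized disk converges to ≈0.91 rather than 1 — the
  same behavior as `skimage.measure.regionprops`. Features are therefore
  internally consistent but not bias-corrected estimates of continuous
  geometry.
* The NRL center is the area centroid; ellipse fits match the region's
  second-order central moments (with the 1/12 single-pixel term) rescaled to
  equal area; angles are degrees in [0°, 180°), counterclockwise from the
  column axis with rows pointing up. A region whose minor-axis moment is at
  the single-pixel floor is reported as degenerate.
* Feature standardization (z-score) always uses training-fold statistics
  only; every cross-validation loop, including those inside selection and
  grid search, re-fits the standardizer per fold.
* mRMR uses the MID (difference) form with equal-frequency binning; all
  ties in selection break lexicographically on feature names, making the
  whole procedure deterministic.
* Mutual information of discrete codes is computed in-package from the
  contingency table (the generic library routine spends ~99% of its time on
  input validation at this call granularity); tests cross-check it against
  `sklearn.metrics.mutual_info_score`.
* Fold assignment is stratified (class proportions preserved per fold);
  folds partition tumors, never ROIs, so all tiles of a tumor are on one
  side of every split. ROC curves sweep the tumor-level malignant score
  (mean tile posterior for the multi-ROI arm, the calibrated/fused
  posterior for the others); AUC is trapezoidal, which equals the
  Mann–Whitney statistic.
* MCC is 0 when its denominator vanishes; vacuous rates (0/0) are 1.
* Tumors too small to contain a single tile fall back to their bounding
  rectangle as one ROI, with a logged warning.

## Synthetic phantoms

The clinical cohort the method was designed around (110 images, 64 benign /
46 malignant, tumor maximum diameters 14.7 ± 6.0 mm, 0.1 mm/px) is not
publicly deposited, so the package ships a generator that emulates what the
pipeline actually consumes — second-order gray-level statistics inside a
known outline:

* geometry is drawn in millimetres (diameters from a normal with the cohort
  mean/SD, truncated to 6–28 mm so images stay a tractable size) and only
  rasterized at the requested spacing;
* benign tumors are smooth ellipses (axis ratio 1.1–1.7) with one
  homogeneous interior texture; malignant tumors have spiculated contours
  (three random-phase radial harmonics, relative amplitude 0.18–0.32) and
  2–4 Voronoi texture regions whose speckle correlation lengths differ from
  each other and from the benign interior;
* speckle is multiplicative and Rayleigh-like: the envelope of two
  independent smoothed Gaussian fields, normalized to unit mean, times a
  compartment mean level (hypoechoic tumor vs brighter background,
  separation scaled by `texture_contrast`).

What the phantoms do **not** model: attenuation, shadowing, time-gain
compensation, out-of-plane effects, outline uncertainty, or the biological
overlap between benign and malignant appearance. Class signal is therefore
cleanly learnable by construction, and phantom-study accuracies near 100%
say that the pipeline machinery is correct and leak-free — not that clinical
performance would be similar. Conversely, a pipeline bug (leakage,
mis-voting, broken calibration) would show up as a violated ordering or
below-chance arm.

## Problem sizes

The reference phantom study (`busfusion.study`) uses the full cohort
geometry (110 cases) with a coarse step-10 (σ, C) grid, incremental
selection depth 15, and 8 training tiles per tumor. These sizes keep one
complete study to a few minutes on a single core; the methodology (mRMR →
incremental grouping → backward elimination → grid search → Platt → voting →
fusion, all inside each CV fold) is identical to the full-scale protocol,
which is available by setting `grid_step: 1`, `top_l_max: null`,
`max_train_rois_per_tumor: null`.

## Known limitations

* Undulation (MF9) operationalizes "number of boundary concavity segments"
  with a configurable 0.3 mm hull-distance threshold; published roundness /
  undulation definitions vary between sources and this variant should be
  treated as such.
* The per-ROI training set inherits the tumor-level class balance but not
  ROI-level balance (large malignant tumors contribute more tiles); the
  per-tumor tile cap limits, but does not remove, this effect.
* Whether selection should use folds independent of the final evaluation
  folds is a genuine protocol ambiguity; here selection runs inside each
  outer training fold with its own inner folds (no test information leaks),
  which is the conservative reading.
* The two fused decision values are Platt posteriors in [0, 1]; modeling
  them as Gaussians is a convenient approximation that degrades near the
  interval ends (where the variance floor takes over).
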