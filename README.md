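# busfusion

Computer-aided classification of breast tumors in B-mode ultrasound (BUS)
images, for researchers building or benchmarking BUS CAD pipelines.

Conventional BUS texture analysis extracts gray-level co-occurrence (GLCM)
features from a *single* region of interest — the minimum bounding rectangle
around the tumor — which mixes tumor and surrounding tissue and averages
away local texture variation. `busfusion` implements the multiple-ROI
alternative and its probabilistic combination with shape analysis:

1. **Multiple-ROI texture arm** — the tumor is tiled into nonoverlapping
   1 × 1 mm ROIs (10 × 10 px at 0.1 mm/px). Each ROI yields 320 GLCM
   features (20 statistics TF1–TF20 × distances d ∈ {1..4} × orientations
   θ ∈ {0°, 45°, 90°, 135°}), is classified by an RBF-kernel SVM
   (k(x, x′) = exp(−‖x−x′‖²/2σ²)) with Platt-calibrated posteriors, and the
   tumor is called malignant iff strictly more than 50 % of its ROIs are.
2. **Morphology arm** — 18 whole-tumor descriptors MF1–MF18 (area,
   perimeter, form factor, convexity, solidity, best-fit-ellipse features,
   normalized-radial-length entropy/variance, …) feed a second calibrated
   SVM.
3. **Decision fusion** — the two arms' posterior malignant likelihoods
   d₁, d₂ are combined with a Gaussian Naive-Bayes rule
   ŷ = argmax_y P(y) ∏ᵢ P(dᵢ | y), with per-class Gaussian class-conditionals
   fitted by maximum likelihood on training tumors.

Feature selection is two-phase (mRMR ranking → incremental top-l grouping →
backward elimination), (σ, C) come from an exhaustive integer grid search,
and evaluation is a tumor-level stratified fivefold cross-validation of five
arms (single-ROI texture, morphology, combined, multiple-ROI texture,
fused) with confusion-matrix metrics, ROC/AUC and paired t-tests.

Because the clinical dataset this design targets (110 images, 64 benign /
46 malignant) is not publicly available, the package includes a synthetic
phantom generator — smooth, texture-homogeneous benign ellipses vs
spiculated, texture-heterogeneous malignant shapes on speckle-like
backgrounds — so the whole pipeline is testable end to end. See
`docs/methods.md` for the model details and what phantom results do and do
not demonstrate.

## Worked example

```bash
busfusion simulate --n-benign 3 --n-malignant 2 --seed 11 --out-dir demo_cohort
```

```python
from busfusion import read_cohort, prepare_case, PipelineConfig
from busfusion.roi import tile_tumor

cases = read_cohort("demo_cohort")
case = cases[-1]
print("case:", case.case_id, "label:", case.label, "image:", case.image.shape)
ts = tile_tumor(case.mask, 1.0)
print("tiles:", len(ts), "coverage: %.2f" % ts.coverage_fraction)
prep = prepare_case(case, PipelineConfig())
print("texture features per tile:", prep.roi_table.shape[1] - 4)
print("morphology MF18 (NRL variance): %.4f" % prep.morphology["MF18"])
```

prints

```
case: malignant_001 label: malignant image: (294, 294)
tiles: 146 coverage: 0.81
texture features per tile: 320
morphology MF18 (NRL variance): 0.0181
```

i.e. this 294 × 294 px phantom tumor admits 146 fully interior 1 × 1 mm
tiles covering 81 % of its area, each described by the 320 GLCM features,
and its spiculated contour shows an NRL variance of 0.018 (a smooth benign
contour of the same size is typically several times lower).

A complete five-arm cross-validated study on a small synthetic cohort
(coarse grid; a couple of minutes on one core):

```bash
cat > study.yaml <<EOF
grid_step: 10
top_l_max: 15
max_train_rois_per_tumor: 8
EOF
busfusion run-all --n-benign 16 --n-malignant 12 --seed 7 \
    --config study.yaml --out-dir demo_run
```

```
texture_singleROI    accuracy 0.929 AUC 0.911
morphology           accuracy 0.964 AUC 1.000
combined             accuracy 0.964 AUC 1.000
texture_multiROI     accuracy 1.000 AUC 1.000
fused                accuracy 1.000 AUC 1.000
```

Each line is the pooled cross-validated accuracy and AUC of one arm on the
28 phantoms; the expected ordering — single-ROI texture weakest, multi-ROI
texture and fusion strongest — reflects that tiling avoids diluting local
texture with background, and that fusion can only sharpen two agreeing
arms. `demo_run/report.json` holds per-arm confusion counts, all six
metrics, per-fold accuracies, fusion parameters and paired t-tests.

The CLI also exposes the individual stages (`extract-features`, `select`,
`train`, `evaluate`, `fuse`); run `busfusion --help`.

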