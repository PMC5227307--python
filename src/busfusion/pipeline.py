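"""End-to-end orchestration of the five classification arms.

For every tumor the pipeline prepares (after resampling to the canonical
spacing):

* the texture vector of the single bounding-rectangle ROI (conventional arm),
* the morphology vector MF1..MF18,
* their concatenation (combined arm),
* the per-tile texture table of the 1 x 1 mm tiling (multiple-ROI arm).

Evaluation is a tumor-level stratified K-fold cross-validation: within each
fold, feature selection (unless bypassed) and SVM tuning (unless fixed) are
performed on the training tumors only, the four base arms classify the test
tumors, and the fusion arm combines the multiple-ROI and morphology
posterior malignant likelihoods with a Gaussian Naive-Bayes model fitted on
the training tumors' decisions.  Tumors whose tiling is empty (tumor smaller
than one tile) fall back to their bounding rectangle as a single ROI, with a
logged warning.

All randomness derives from one top-level seed: fold assignment, per-fold
sub-sampling of training tiles and inner-CV shuffles use seeds derived from
it, so a rerun with the same cohort, config and seed reproduces the report
byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    TrainedClassifier,
    TumorDecision,
    classify_rois,
    classify_tumor,
    default_grid,
    grid_search_svm,
    svm_cv_error,
    train_svm_platt,
    vote_tumor,
)
from .config import ARMS, PipelineConfig
from .errors import DataError
from .evaluation import (
    ConfusionCounts,
    binomial_above_chance,
    metrics,
    paired_t_test,
    roc_auc,
    stratified_folds,
)
from .fusion import fit_fusion, fuse
from .imaging import BUSCase, quantize_gray_levels, resample_to_spacing
from .morphology import morph_vector
from .roi import bounding_rectangle, tile_tumor
from .selection import select_features
from .texture import texture_table, texture_vector

logger = logging.getLogger("busfusion")

__all__ = ["PreparedCase", "prepare_case", "run_pipeline"]


@dataclass
class PreparedCase:
    """All per-tumor feature tables needed by the five arms."""

    case_id: str
    label: str
    n_tiles: int
    roi_table: pd.DataFrame          # per-tile texture features (>= 1 row)
    single_texture: pd.Series        # bounding-rectangle texture vector
    morphology: pd.Series            # MF1..MF18
    combined: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.combined = pd.concat([self.single_texture, self.morphology])


def _derived_seed(seed: int, stream: int) -> int:
    return int((seed * 100003 + 17 * stream + 1) % (2**31 - 1))


def prepare_case(case: BUSCase, config: PipelineConfig) -> PreparedCase:
    """Resample, tile and featurize one tumor."""
    case = resample_to_spacing(case, config.target_spacing_mm)
    quant = quantize_gray_levels(case.image, config.glcm_levels)
    tiles = tile_tumor(case.mask, config.roi_side_mm, config.min_inside_fraction)
    rect = bounding_rectangle(case.mask)
    kwargs = dict(
        d_set=config.distances,
        theta_set=config.angles_deg,
        G=config.glcm_levels,
        symmetric=config.glcm_symmetric,
    )
    single = texture_vector(quant, rect, **kwargs)
    if len(tiles) > 0:
        roi_tab = texture_table(quant, list(tiles.tiles), case_id=case.case_id, **kwargs)
    else:
        logger.warning(
            "case %s: no %0.1f mm tile fits inside the tumor; "
            "falling back to the bounding rectangle as a single ROI",
            case.case_id, config.roi_side_mm,
        )
        roi_tab = single.to_frame().T
        roi_tab.insert(0, "case_id", case.case_id)
        roi_tab.insert(1, "row0", rect[0])
        roi_tab.insert(2, "col0", rect[1])
        roi_tab.insert(3, "side_px", max(rect[2], rect[3]))
    morph = morph_vector(
        case.mask,
        undulation_threshold_mm=config.undulation_threshold_mm,
        nrl_bins=config.nrl_bins,
        on_multicomponent="largest",
    )
    return PreparedCase(
        case_id=case.case_id,
        label=case.label,
        n_tiles=len(tiles),
        roi_table=roi_tab,
        single_texture=single,
        morphology=morph,
    )


def _subsample_rois(tables: list[pd.DataFrame], cap: int | None,
                    rng: np.random.Generator) -> pd.DataFrame:
    parts = []
    for tab in tables:
        if cap is not None and len(tab) > cap:
            idx = rng.choice(len(tab), size=cap, replace=False)
            parts.append(tab.iloc[np.sort(idx)])
        else:
            parts.append(tab)
    return pd.concat(parts, ignore_index=True)


def _fit_arm(
    arm: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray | None,
    config: PipelineConfig,
    seed: int,
) -> tuple[TrainedClassifier, dict]:
    """Feature selection + SVM tuning + Platt training for one arm."""
    feature_cols = [c for c in table.columns
                    if c not in ("case_id", "row0", "col0", "side_px")]
    features = table.loc[:, feature_cols]

    bypass = (config.bypass_features or {}).get(arm)
    if bypass:
        missing = [c for c in bypass if c not in features.columns]
        if missing:
            raise DataError(f"{arm}: bypass features not in table: {missing}")
        selected = tuple(bypass)
        selection_info = {"bypassed": True, "final": list(selected)}
    else:
        def evaluator(cols) -> float:
            return svm_cv_error(
                features.loc[:, list(cols)].to_numpy(dtype=float), labels,
                config.selection_sigma, config.selection_C,
                n_folds=config.selection_folds, seed=seed, groups=groups,
            )

        ranking, candidate, final = select_features(
            features, labels, evaluator,
            n_bins=config.selection_bins, top_l_max=config.top_l_max,
        )
        selected = final.features
        selection_info = {
            "bypassed": False,
            "ranking": list(ranking.names),
            "candidate": list(candidate.features),
            "candidate_error": candidate.cv_error,
            "final": list(selected),
            "final_error": final.cv_error,
        }

    X = features.loc[:, list(selected)].to_numpy(dtype=float)
    fixed = (config.fixed_svm_params or {}).get(arm)
    if fixed:
        sigma, C = fixed
    else:
        grid = default_grid(config.grid_step)
        sigma, C = grid_search_svm(
            X, labels, n_folds=config.selection_folds, seed=seed,
            sigma_grid=grid, C_grid=grid, groups=groups,
        )
    clf = train_svm_platt(
        pd.DataFrame(X, columns=list(selected)), labels, sigma, C,
        seed=seed, platt_folds=config.platt_folds,
    )
    info = {"selection": selection_info, "sigma": float(sigma), "C": float(C)}
    return clf, info


def _multi_roi_decision(clf: TrainedClassifier, prep: PreparedCase) -> TumorDecision:
    decisions = classify_rois(clf, prep.roi_table)
    return vote_tumor(decisions, case_id=prep.case_id)


def run_pipeline(
    cases: list[BUSCase],
    config: PipelineConfig | None = None,
    seed: int = 0,
    prepared: list[PreparedCase] | None = None,
) -> dict:
    """Run the full five-arm cross-validated study on a cohort.

    Returns a JSON-serializable report with per-arm pooled confusion counts,
    the six headline metrics, ROC/AUC data, per-fold accuracies, paired
    t-tests of the fused arm against the other four, and the resolved
    configuration.  ``prepared`` can carry pre-featurized cases (e.g. from
    the CLI ``extract-features`` stage) to skip re-extraction.
    """
    config = config or PipelineConfig()
    if prepared is None:
        prepared = [prepare_case(c, config) for c in cases]
    labels = np.array([p.label for p in prepared])
    if (labels == "unknown").any():
        raise DataError("all cases must be labeled for evaluation")

    folds = stratified_folds(labels, config.cv_folds, seed)
    decisions: dict[str, dict[str, TumorDecision]] = {arm: {} for arm in ARMS}
    fold_info: list[dict] = []

    for k in range(config.cv_folds):
        tr = np.nonzero(folds != k)[0]
        te = np.nonzero(folds == k)[0]
        fseed = _derived_seed(seed, k)
        rng = np.random.default_rng(fseed)
        info: dict = {"fold": k, "arms": {}}

        # ---- tumor-level arms -------------------------------------------
        arm_tables = {
            "texture_singleROI": pd.DataFrame([prepared[i].single_texture for i in tr]),
            "morphology": pd.DataFrame([prepared[i].morphology for i in tr]),
            "combined": pd.DataFrame([prepared[i].combined for i in tr]),
        }
        arm_clf: dict[str, TrainedClassifier] = {}
        for arm, table in arm_tables.items():
            clf, arm_info = _fit_arm(arm, table, labels[tr], None, config, fseed)
            arm_clf[arm] = clf
            info["arms"][arm] = arm_info
        # ---- multiple-ROI texture arm -----------------------------------
        roi_train = _subsample_rois(
            [prepared[i].roi_table for i in tr], config.max_train_rois_per_tumor, rng
        )
        label_of = {prepared[i].case_id: labels[i] for i in range(len(prepared))}
        roi_labels = roi_train["case_id"].map(label_of).to_numpy()
        roi_groups = roi_train["case_id"].to_numpy()
        clf_multi, arm_info = _fit_arm(
            "texture_multiROI", roi_train, roi_labels, roi_groups, config, fseed
        )
        arm_clf["texture_multiROI"] = clf_multi
        info["arms"]["texture_multiROI"] = arm_info

        # ---- test-fold decisions ----------------------------------------
        for i in te:
            prep = prepared[i]
            decisions["texture_singleROI"][prep.case_id] = classify_tumor(
                arm_clf["texture_singleROI"], prep.single_texture,
                case_id=prep.case_id, arm="texture_singleROI")
            decisions["morphology"][prep.case_id] = classify_tumor(
                arm_clf["morphology"], prep.morphology,
                case_id=prep.case_id, arm="morphology")
            decisions["combined"][prep.case_id] = classify_tumor(
                arm_clf["combined"], prep.combined,
                case_id=prep.case_id, arm="combined")
            decisions["texture_multiROI"][prep.case_id] = \
                _multi_roi_decision(clf_multi, prep)

        # ---- fusion: fit on training-fold decisions, apply to test ------
        train_pairs = np.array([
            [_multi_roi_decision(clf_multi, prepared[i]).p_malignant,
             classify_tumor(arm_clf["morphology"], prepared[i].morphology).p_malignant]
            for i in tr
        ])
        fusion_model = fit_fusion(
            train_pairs, labels[tr],
            variance_floor=config.variance_floor, variant=config.fusion_variant,
        )
        for i in te:
            prep = prepared[i]
            d1 = decisions["texture_multiROI"][prep.case_id].p_malignant
            d2 = decisions["morphology"][prep.case_id].p_malignant
            decisions["fused"][prep.case_id] = fuse(
                fusion_model, d1, d2, case_id=prep.case_id)
        info["fusion"] = {
            "priors": fusion_model.priors.tolist(),
            "means": fusion_model.means.tolist(),
            "variances": fusion_model.variances.tolist(),
        }
        fold_info.append(info)

    # ---- pooled evaluation ----------------------------------------------
    case_ids = [p.case_id for p in prepared]
    report: dict = {
        "seed": seed,
        "n_cases": len(prepared),
        "n_benign": int((labels == "benign").sum()),
        "n_malignant": int((labels == "malignant").sum()),
        "fold_assignment": {cid: int(f) for cid, f in zip(case_ids, folds)},
        "arms": {},
        "folds": fold_info,
        "config": config.as_dict(),
    }
    chance = max((labels == "benign").mean(), (labels == "malignant").mean())
    fold_acc: dict[str, list[float]] = {}
    for arm in ARMS:
        arm_dec = decisions[arm]
        pred = [arm_dec[cid].predicted for cid in case_ids]
        counts = ConfusionCounts.from_predictions(labels, pred)
        rep = metrics(counts)
        scores = [arm_dec[cid].score_malignant for cid in case_ids]
        roc_pts, auc = roc_auc(scores, labels)
        accs = []
        for k in range(config.cv_folds):
            sel = folds == k
            ok = [arm_dec[cid].predicted == lab
                  for cid, lab in zip(np.array(case_ids)[sel], labels[sel])]
            accs.append(float(np.mean(ok)))
        fold_acc[arm] = accs
        report["arms"][arm] = {
            "counts": {"TP": counts.TP, "TN": counts.TN,
                       "FP": counts.FP, "FN": counts.FN},
            "metrics": rep.as_dict(),
            "auc": auc,
            "roc_points": roc_pts.tolist(),
            "fold_accuracies": accs,
            "binomial_p_above_chance": binomial_above_chance(
                counts.TP + counts.TN, counts.total, chance),
            "decisions": {
                cid: {"predicted": arm_dec[cid].predicted,
                      "posterior": arm_dec[cid].posterior,
                      "p_malignant": arm_dec[cid].p_malignant}
                for cid in case_ids
            },
        }
    report["t_tests"] = {
        f"fused_vs_{arm}": dict(zip(("t", "p"),
                                    paired_t_test(fold_acc["fused"], fold_acc[arm])))
        for arm in ARMS if arm != "fused"
    }
    return report
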