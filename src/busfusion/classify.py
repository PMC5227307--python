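"""Per-ROI and per-tumor SVM classification.

The classifier is a binary RBF-kernel SVM; the kernel is written as
``exp(-||x - x'||^2 / (2 sigma^2))``, so sklearn's ``gamma`` is
``1 / (2 sigma^2)``.  (sigma, C) are tuned by exhaustive grid search over the
integer grid 1 < sigma < 100, 1 < C < 100 (step configurable) maximizing
mean cross-validated accuracy, ties resolved toward the smallest C then the
smallest sigma.

Features are z-scored with statistics estimated on training data only; every
cross-validation routine here re-fits the standardizer inside each training
fold (leakage guard).  Posterior class probabilities come from Platt's
sigmoid ``P(malignant | m) = 1 / (1 + exp(A m + B))`` fitted on 3-fold
cross-validated decision margins of the training set, using the
Newton-with-backtracking algorithm of Lin, Lin & Weng (2007).

The positive class is *malignant* (+1) throughout; sensitivity downstream is
the malignant detection rate.

Tumor-level rules:

* multiple-ROI arm: each tile is classified independently; the tumor is
  malignant iff strictly more than 50% of its tiles are malignant (an exact
  tie is benign), and the tumor posterior is the mean posterior of the tiles
  that agree with the winning class;
* single-vector arms (morphology, single-ROI texture, combined): the tumor
  decision is the classifier decision on the whole-tumor feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.svm import SVC

# The grid search and selection evaluators perform thousands of small SVM
# fits; sklearn's per-call input validation dominates their cost.  Inputs are
# validated once at the module boundary instead.
_fast_sklearn = lambda: sklearn.config_context(  # noqa: E731
    assume_finite=True, skip_parameter_validation=True
)

from .errors import DataError

__all__ = [
    "ROIDecision",
    "TumorDecision",
    "TrainedClassifier",
    "Standardizer",
    "svm_cv_error",
    "grid_search_svm",
    "train_svm_platt",
    "classify_rois",
    "vote_tumor",
    "classify_tumor",
    "default_grid",
]

LABELS = ("benign", "malignant")


def encode_labels(labels) -> np.ndarray:
    """Map benign/malignant (or -1/+1) labels to {-1, +1} ints."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iufb":
        out = np.where(arr.astype(float) > 0, 1, -1)
    else:
        bad = set(np.unique(arr)) - set(LABELS)
        if bad:
            raise DataError(f"unknown labels: {sorted(bad)}")
        out = np.where(arr == "malignant", 1, -1)
    return out.astype(int)


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-scoring with training-set statistics."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean, sd)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _make_svc(sigma: float, C: float) -> SVC:
    return SVC(C=C, kernel="rbf", gamma=1.0 / (2.0 * sigma**2))


def _cv_splits(y: np.ndarray, n_folds: int, seed: int, groups: np.ndarray | None):
    # Clamp the fold count to the smallest class (or group-class) size so tiny
    # data sets remain splittable; full-scale runs are unaffected.
    if groups is None:
        min_count = int(np.bincount((y > 0).astype(int)).min())
    else:
        min_count = min(
            len(set(groups[y > 0])), len(set(groups[y < 0]))
        )
    if min_count < 2:
        raise DataError("cross-validation needs at least two units per class")
    k = max(2, min(n_folds, min_count))
    if groups is None:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros_like(y), y))
    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros_like(y), y, groups))


def svm_cv_error(
    X: np.ndarray,
    y,
    sigma: float,
    C: float,
    n_folds: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> float:
    """Mean cross-validated misclassification rate of the RBF-SVM.

    Standardization statistics are fitted on each training fold only; when
    ``groups`` is given (ROI-level data grouped by tumor), folds never split
    a group across train and test.
    """
    y = encode_labels(y)
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    if not np.isfinite(X).all():
        raise DataError("non-finite feature values")
    errors = []
    with _fast_sklearn():
        for tr, te in _cv_splits(y, n_folds, seed, groups):
            if len(np.unique(y[tr])) < 2:
                errors.append(float(np.mean(y[te] != y[tr][0])))
                continue
            std = Standardizer.fit(X[tr])
            clf = _make_svc(sigma, C)
            clf.fit(std.apply(X[tr]), y[tr])
            pred = clf.predict(std.apply(X[te]))
            errors.append(float(np.mean(pred != y[te])))
    return float(np.mean(errors))


def default_grid(step: int = 1) -> np.ndarray:
    """The integer parameter grid 1 < value < 100 with the given step."""
    return np.arange(2, 100, step)


def grid_search_svm(
    X: np.ndarray,
    y,
    n_folds: int = 5,
    seed: int = 0,
    sigma_grid: np.ndarray | None = None,
    C_grid: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> tuple[float, float]:
    """Exhaustive (sigma, C) grid search maximizing mean CV accuracy.

    Ties are broken toward the smallest C, then the smallest sigma.  Folds
    and per-fold standardization are computed once and reused across the
    grid for speed.
    """
    y = encode_labels(y)
    if len(np.unique(y)) < 2:
        raise DataError("grid search needs both classes present")
    sigma_grid = default_grid() if sigma_grid is None else np.asarray(sigma_grid)
    C_grid = default_grid() if C_grid is None else np.asarray(C_grid)
    splits = _cv_splits(y, n_folds, seed, groups)
    folds = []
    for tr, te in splits:
        std = Standardizer.fit(X[tr])
        folds.append((std.apply(X[tr]), y[tr], std.apply(X[te]), y[te]))
    best = None  # (neg_acc, C, sigma) lexicographic minimization
    with _fast_sklearn():
        for C in np.sort(C_grid):
            for sigma in np.sort(sigma_grid):
                accs = []
                for Xtr, ytr, Xte, yte in folds:
                    if len(np.unique(ytr)) < 2:
                        accs.append(float(np.mean(yte == ytr[0])))
                        continue
                    clf = _make_svc(sigma, C)
                    clf.fit(Xtr, ytr)
                    accs.append(float(np.mean(clf.predict(Xte) == yte)))
                key = (-float(np.mean(accs)), float(C), float(sigma))
                if best is None or key < best:
                    best = key
    assert best is not None
    return best[2], best[1]


def _platt_fit(margins: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid parameters (A, B) on decision margins.

    Newton's method with backtracking line search on the regularized
    log-likelihood (Lin, Lin & Weng 2007); targets are smoothed class
    frequencies as in Platt (1999).
    """
    y = np.asarray(y)
    n_pos = int((y > 0).sum())
    n_neg = len(y) - n_pos
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y > 0, hi, lo)
    f = np.asarray(margins, dtype=np.float64)

    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))

    def objective(a: float, b: float) -> float:
        # With p = 1/(1+e^z), the NLL is sum log(1+e^z) - (1-t) z (stable form).
        z = a * f + b
        return float(np.sum(np.logaddexp(0.0, z) - (1.0 - t) * z))

    obj = objective(A, B)
    for _ in range(100):
        z = A * f + B
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # P(y=+1 | margin)
        # dL/dz = e^z/(1+e^z) - (1-t) = t - p
        d1 = t - p
        d2 = p * (1.0 - p) + 1e-12
        gA = float(np.sum(d1 * f))
        gB = float(np.sum(d1))
        if abs(gA) < 1e-5 and abs(gB) < 1e-5:
            break
        hAA = float(np.sum(d2 * f * f)) + 1e-12
        hAB = float(np.sum(d2 * f))
        hBB = float(np.sum(d2)) + 1e-12
        det = hAA * hBB - hAB * hAB
        if det <= 0:
            break
        dA = -(hBB * gA - hAB * gB) / det
        dB = -(-hAB * gA + hAA * gB) / det
        step = 1.0
        g_dot_d = gA * dA + gB * dB
        while step >= 1e-10:
            newA, newB = A + step * dA, B + step * dB
            new_obj = objective(newA, newB)
            if new_obj < obj + 1e-4 * step * g_dot_d:
                A, B, obj = newA, newB, new_obj
                break
            step /= 2.0
        else:
            break
    return float(A), float(B)


@dataclass
class TrainedClassifier:
    """A tuned RBF-SVM with its standardizer and Platt calibration."""

    sigma: float
    C: float
    feature_names: tuple[str, ...]
    standardizer: Standardizer
    svc: SVC
    platt_A: float
    platt_B: float

    def margins(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.standardizer.apply(np.asarray(X, float)))

    def predict_proba_malignant(self, X: np.ndarray) -> np.ndarray:
        z = np.clip(self.platt_A * self.margins(X) + self.platt_B, -500, 500)
        return 1.0 / (1.0 + np.exp(z))

    def _matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise DataError(f"feature columns missing from table: {missing}")
        return table.loc[:, list(self.feature_names)].to_numpy(dtype=float)

    def save(self, path) -> None:
        """Serialize to a single JSON artifact (schema-versioned).

        The SVM is stored as its training set plus hyperparameters and is
        refitted deterministically on load (libsvm training is exact for a
        fixed dataset), which keeps the artifact a plain-text file.
        """
        import json
        from pathlib import Path

        X_raw = self.standardizer.mean + self._train_X_std * self.standardizer.sd
        payload = {
            "schema_version": 1,
            "sigma": self.sigma,
            "C": self.C,
            "feature_names": list(self.feature_names),
            "platt_A": self.platt_A,
            "platt_B": self.platt_B,
            "train_X": X_raw.tolist(),
            "train_y": self._train_y.tolist(),
        }
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        import json
        from pathlib import Path

        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != 1:
            raise DataError(f"{path}: unsupported model schema")
        X = np.asarray(payload["train_X"], dtype=float)
        y = np.asarray(payload["train_y"], dtype=int)
        std = Standardizer.fit(X)
        svc = _make_svc(payload["sigma"], payload["C"])
        svc.fit(std.apply(X), y)
        clf = cls(
            sigma=payload["sigma"], C=payload["C"],
            feature_names=tuple(payload["feature_names"]),
            standardizer=std, svc=svc,
            platt_A=payload["platt_A"], platt_B=payload["platt_B"],
        )
        clf._train_X_std = std.apply(X)
        clf._train_y = y
        return clf


def train_svm_platt(
    features: pd.DataFrame | np.ndarray,
    labels,
    sigma: float,
    C: float,
    seed: int = 0,
    platt_folds: int = 3,
    feature_names: tuple[str, ...] | None = None,
) -> TrainedClassifier:
    """Train the RBF-SVM and fit its Platt posterior map.

    Calibration margins are produced by ``platt_folds``-fold cross-validation
    inside the training set so the sigmoid never sees margins of points the
    SVM was fitted on; the final SVM is then refitted on all training data.
    """
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = feature_names or tuple(f"f{i}" for i in range(X.shape[1]))
    y = encode_labels(labels)
    if (y > 0).sum() < 2 or (y < 0).sum() < 2:
        raise DataError("training needs at least two samples per class")

    margins = np.empty(len(y))
    folds = _cv_splits(y, platt_folds, seed, None)
    std_all = Standardizer.fit(X)
    for tr, te in folds:
        if len(np.unique(y[tr])) < 2:  # degenerate tiny fold: fall back
            margins[te] = 0.0
            continue
        std = Standardizer.fit(X[tr])
        clf = _make_svc(sigma, C)
        clf.fit(std.apply(X[tr]), y[tr])
        margins[te] = clf.decision_function(std.apply(X[te]))
    A, B = _platt_fit(margins, y)

    svc = _make_svc(sigma, C)
    X_std = std_all.apply(X)
    svc.fit(X_std, y)
    clf = TrainedClassifier(
        sigma=float(sigma), C=float(C), feature_names=names,
        standardizer=std_all, svc=svc, platt_A=A, platt_B=B,
    )
    clf._train_X_std = X_std
    clf._train_y = y
    return clf


@dataclass(frozen=True)
class ROIDecision:
    """Classification of one tile."""

    row0: int
    col0: int
    predicted: str
    p_malignant: float


@dataclass(frozen=True)
class TumorDecision:
    """Tumor-level decision of one analysis arm.

    ``posterior`` is the posterior likelihood of the *winning* class;
    ``p_malignant`` re-expresses it on the malignant scale for fusion and
    ROC analysis.  ``vote_fraction_malignant`` is present only for the
    multiple-ROI texture arm.
    """

    case_id: str
    arm: str
    predicted: str
    posterior: float
    vote_fraction_malignant: float | None = None
    score_malignant: float | None = None

    @property
    def p_malignant(self) -> float:
        return self.posterior if self.predicted == "malignant" else 1.0 - self.posterior


def classify_rois(clf: TrainedClassifier, table: pd.DataFrame) -> list[ROIDecision]:
    """Independent per-tile decisions (order-invariant, deterministic)."""
    if len(table) == 0:
        return []
    p = clf.predict_proba_malignant(clf._matrix(table))
    rows = table["row0"].to_numpy() if "row0" in table else np.zeros(len(table), int)
    cols = table["col0"].to_numpy() if "col0" in table else np.zeros(len(table), int)
    return [
        ROIDecision(int(r), int(c), "malignant" if pi >= 0.5 else "benign", float(pi))
        for r, c, pi in zip(rows, cols, p)
    ]


def vote_tumor(decisions: list[ROIDecision], case_id: str = "",
               arm: str = "texture_multiROI") -> TumorDecision:
    """Majority vote over tile decisions.

    Malignant iff strictly more than half of the tiles are malignant; the
    posterior is the mean posterior (of the winning class) over agreeing
    tiles.  The auxiliary ``score_malignant`` — the mean malignant
    probability over all tiles — is the quantity swept for ROC analysis.
    """
    if not decisions:
        raise DataError(f"{case_id}: cannot vote over zero ROI decisions")
    p = np.array([d.p_malignant for d in decisions])
    mal = np.array([d.predicted == "malignant" for d in decisions])
    frac = float(mal.mean())
    if frac > 0.5:
        winner, posterior = "malignant", float(p[mal].mean())
    else:
        winner, posterior = "benign", float((1.0 - p[~mal]).mean()) if (~mal).any() else 0.5
    return TumorDecision(
        case_id=case_id, arm=arm, predicted=winner, posterior=posterior,
        vote_fraction_malignant=frac, score_malignant=float(p.mean()),
    )


def classify_tumor(clf: TrainedClassifier, vector: pd.Series | pd.DataFrame,
                   case_id: str = "", arm: str = "morphology") -> TumorDecision:
    """Whole-tumor decision from a single feature vector (morphology,
    single-ROI texture, or combined arm)."""
    table = vector.to_frame().T if isinstance(vector, pd.Series) else vector
    p = float(clf.predict_proba_malignant(clf._matrix(table))[0])
    if p >= 0.5:
        return TumorDecision(case_id, arm, "malignant", p, score_malignant=p)
    return TumorDecision(case_id, arm, "benign", 1.0 - p, score_malignant=p)
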