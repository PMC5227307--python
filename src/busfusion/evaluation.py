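"""Performance evaluation: confusion-matrix metrics, ROC/AUC, CV folds,
paired t-tests.

The positive class is malignant.  The six headline metrics are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    PPV         = TP / (TP + FP)
    NPV         = TN / (TN + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the convention that any metric whose denominator is zero is 0 (MCC) or
1 (the rate metrics, a vacuously perfect rate).  Headline numbers are
computed on confusion counts pooled over the test folds of a tumor-level
stratified fivefold cross-validation; folds partition tumors, never ROIs, so
all tiles of a tumor live on one side of every split.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import DataError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "metrics",
    "roc_points",
    "roc_auc",
    "stratified_folds",
    "paired_t_test",
    "binomial_above_chance",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        from .classify import encode_labels

        t = encode_labels(y_true)
        p = encode_labels(y_pred)
        return cls(
            TP=int(((t > 0) & (p > 0)).sum()),
            TN=int(((t < 0) & (p < 0)).sum()),
            FP=int(((t < 0) & (p > 0)).sum()),
            FN=int(((t > 0) & (p < 0)).sum()),
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricReport:
    accuracy: float
    specificity: float
    sensitivity: float
    PPV: float
    NPV: float
    MCC: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else 1.0


def metrics(counts: ConfusionCounts) -> MetricReport:
    """The six confusion-matrix metrics (zero denominators per module rules)."""
    if counts.total == 0:
        raise DataError("empty confusion matrix")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom2) if denom2 > 0 else 0.0
    return MetricReport(
        accuracy=(tp + tn) / counts.total,
        specificity=_rate(tn, tn + fp),
        sensitivity=_rate(tp, tp + fn),
        PPV=_rate(tp, tp + fp),
        NPV=_rate(tn, tn + fn),
        MCC=float(mcc),
    )


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve as (FPR, TPR) rows from a sweep over the unique scores.

    Thresholds run from above the maximum score (nothing called malignant)
    downwards, calling malignant every tumor whose score is >= threshold.
    """
    from .classify import encode_labels

    s = np.asarray(scores, dtype=float)
    y = encode_labels(labels)
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC needs at least one tumor of each class")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted > 0)
    fps = np.cumsum(y_sorted < 0)
    # Keep the last index of each tied score block.
    last = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[last] / n_pos])
    fpr = np.concatenate([[0.0], fps[last] / n_neg])
    return np.column_stack([fpr, tpr])


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC."""
    pts = roc_points(scores, labels)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def stratified_folds(labels, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per tumor from a seeded stratified K-fold partition."""
    from .classify import encode_labels

    y = encode_labels(labels)
    counts = np.bincount((y > 0).astype(int))
    if counts.min() < n_folds:
        raise DataError(
            f"need at least {n_folds} tumors per class for {n_folds} stratified folds"
        )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for k, (_, test) in enumerate(cv.split(np.zeros_like(y), y)):
        assignment[test] = k
    return assignment


def paired_t_test(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on fold-wise accuracies.

    All-zero differences report (0.0, 1.0); zero-variance nonzero differences
    report an infinite t with p = 0.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise DataError("paired t-test needs two equal-length vectors, n >= 2")
    diff = a - b
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    if np.isclose(diff.std(ddof=1), 0.0):
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def binomial_above_chance(n_correct: int, n_total: int, p_chance: float) -> float:
    """One-sided binomial p-value that an accuracy exceeds a chance rate."""
    return float(stats.binomtest(n_correct, n_total, p_chance,
                                 alternative="greater").pvalue)


def plot_roc_curves(report: dict, out_path) -> None:
    """Render the per-arm ROC curves of a pipeline report to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for arm, arm_rep in report["arms"].items():
        pts = np.asarray(arm_rep["roc_points"])
        ax.plot(pts[:, 0], pts[:, 1], label=f"{arm} (AUC {arm_rep['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
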