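"""Two-phase feature selection.

Phase 1 ranks features with the minimal-redundancy-maximal-relevance (mRMR)
criterion in its MID (mutual-information difference) form: the first feature
maximizes relevance MI(f; y); each subsequent feature maximizes
``MI(f; y) - mean_{s in selected} MI(f; s)``.  The top-l groups (l = 1..L)
are then evaluated with a cross-validated classifier and the smallest group
attaining the minimum error becomes the candidate subset.

Phase 2 applies backward elimination to the candidate: the single feature
whose removal gives the lowest CV error is removed repeatedly, until every
possible removal would strictly increase the error.  The final error is
therefore never worse than the candidate's.

Continuous features are discretized with equal-frequency binning (default 10
bins) before mutual information is computed; ties everywhere are broken by
lexicographic feature-name order so the procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "FeatureRanking",
    "SelectedSubset",
    "mutual_information",
    "mrmr_rank",
    "incremental_select",
    "backward_eliminate",
    "select_features",
]

Evaluator = Callable[[Sequence[str]], float]


@dataclass(frozen=True)
class FeatureRanking:
    """mRMR-ordered feature names with their greedy scores."""

    names: tuple[str, ...]
    scores: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class SelectedSubset:
    """A selected feature subset and the CV error it achieved."""

    features: tuple[str, ...]
    cv_error: float
    phase: str  # "candidate" or "final"

    def __len__(self) -> int:
        return len(self.features)


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to a single bin."""
    x = np.asarray(x, dtype=np.float64)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def _codes(labels: np.ndarray) -> np.ndarray:
    """Dense non-negative integer codes for an arbitrary discrete array."""
    _, inv = np.unique(np.asarray(labels), return_inverse=True)
    return inv


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two dense-coded discrete arrays."""
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    p = np.bincount(a * kb + b, minlength=ka * kb).astype(float).reshape(ka, kb)
    p /= p.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (pa @ pb)[nz])).sum())


def mutual_information(
    feature: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> float:
    """MI (nats) between an equal-frequency-binned feature and labels.

    A constant feature has zero mutual information with anything.
    """
    feature = np.asarray(feature)
    if feature.size < 2:
        raise DataError("mutual information needs at least two samples")
    codes = _discretize(feature, n_bins)
    return _mi_discrete(_codes(labels), _codes(codes))


def mrmr_rank(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_bins: int = 10,
    top_k: int | None = None,
) -> FeatureRanking:
    """Greedy mRMR (MID) ranking of the columns of ``table``.

    ``top_k`` truncates the ranking (the remaining order is not needed when
    only the top-l groups will be evaluated).
    """
    names = list(table.columns)
    if len(names) < 1:
        raise DataError("feature table is empty")
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise DataError("mRMR needs at least two samples of each class")
    y_codes = _codes(y)
    binned = {c: _codes(_discretize(table[c].to_numpy(), n_bins)) for c in names}
    relevance = {c: _mi_discrete(y_codes, binned[c]) for c in names}

    k_max = len(names) if top_k is None else min(top_k, len(names))
    selected: list[str] = []
    scores: list[float] = []
    remaining = sorted(names)  # lexicographic base order = deterministic ties
    # Cache of redundancy sums MI(f, s) accumulated as features are selected.
    red_sum = {c: 0.0 for c in names}
    while len(selected) < k_max:
        best_name, best_score = None, -np.inf
        for c in remaining:
            if selected:
                score = relevance[c] - red_sum[c] / len(selected)
            else:
                score = relevance[c]
            if score > best_score + 1e-12:
                best_name, best_score = c, score
        assert best_name is not None
        selected.append(best_name)
        scores.append(best_score)
        remaining.remove(best_name)
        for c in remaining:
            red_sum[c] += _mi_discrete(binned[best_name], binned[c])
    return FeatureRanking(tuple(selected), tuple(scores))


def incremental_select(
    ranking: FeatureRanking | Sequence[str],
    evaluator: Evaluator,
    L: int | None = None,
) -> SelectedSubset:
    """Evaluate the top-l ranked groups and keep the smallest argmin.

    Returns the smallest l (1 <= l <= L) whose CV error equals the global
    minimum over all evaluated group sizes.
    """
    names = list(ranking.names if isinstance(ranking, FeatureRanking) else ranking)
    if not names:
        raise DataError("empty ranking")
    L = len(names) if L is None else min(L, len(names))
    errors = [evaluator(names[:l]) for l in range(1, L + 1)]
    best = min(errors)
    l_star = 1 + errors.index(best)  # first == smallest group at the minimum
    return SelectedSubset(tuple(names[:l_star]), float(best), "candidate")


def backward_eliminate(candidate: SelectedSubset, evaluator: Evaluator) -> SelectedSubset:
    """Sequentially drop features while the CV error does not increase.

    At each step the removal with the lowest error is applied (ties: drop the
    lexicographically last name); the loop stops when every possible removal
    would strictly increase the error, so the final subset is never empty and
    its error never exceeds the candidate's.
    """
    current = list(candidate.features)
    if not current:
        raise DataError("candidate subset is empty")
    current_err = candidate.cv_error
    while len(current) > 1:
        trials = []
        for name in sorted(current, reverse=True):
            kept = [c for c in current if c != name]
            trials.append((evaluator(kept), name, kept))
        err, _, kept = min(trials, key=lambda t: (t[0],))
        if err > current_err:
            break
        current, current_err = kept, err
    return SelectedSubset(tuple(current), float(current_err), "final")


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    evaluator: Evaluator,
    n_bins: int = 10,
    top_l_max: int | None = None,
) -> tuple[FeatureRanking, SelectedSubset, SelectedSubset]:
    """Run the full two-phase selection; returns (ranking, candidate, final)."""
    ranking = mrmr_rank(table, labels, n_bins=n_bins, top_k=top_l_max)
    candidate = incremental_select(ranking, evaluator, L=top_l_max)
    final = backward_eliminate(candidate, evaluator)
    assert final.cv_error <= candidate.cv_error + 1e-12
    return ranking, candidate, final
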