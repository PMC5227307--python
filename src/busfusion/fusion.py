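"""Probabilistic fusion of per-arm tumor decisions.

The two analysis arms (multiple-ROI texture, morphology) each yield a
posterior malignant likelihood d_i for a tumor.  Treating the arms as
mutually independent given the class, the fused posterior is

    P(y | d_1..d_L)  proportional to  P(y) * prod_i P(d_i | y),

with each class-conditional P(d_i | y) a univariate Gaussian whose mean and
variance are maximum-likelihood estimates from training-fold decision values
(class priors = class frequencies).  The predicted class is the argmax; an
exact tie goes to benign.  All densities are evaluated in the log domain, so
inputs hundreds of standard deviations from a class mean cannot underflow.

The factorized (naive) form is the default; a full per-class covariance
variant over the L-vector of decisions is available for comparison
(``variant="full"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .classify import TumorDecision
from .errors import DataError

__all__ = ["FusionModel", "fit_fusion", "fuse"]

_CLASSES = (-1, 1)  # benign, malignant


@dataclass(frozen=True)
class FusionModel:
    """Class priors and per-arm, per-class Gaussian likelihood parameters.

    ``means``/``variances`` have shape (2, L): rows index the class
    (benign = row 0, malignant = row 1), columns the contributing
    classifier.  For ``variant="full"``, ``covariances`` holds one (L, L)
    matrix per class and the factorized parameters are its diagonal.
    """

    priors: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    variant: str = "naive"
    covariances: np.ndarray | None = None

    @property
    def n_arms(self) -> int:
        return self.means.shape[1]


def fit_fusion(
    decision_pairs: np.ndarray,
    labels,
    variance_floor: float = 1e-6,
    variant: str = "naive",
) -> FusionModel:
    """Maximum-likelihood fit of the fusion model.

    ``decision_pairs`` is an (n, L) array of per-arm posterior malignant
    likelihoods of training tumors; ``labels`` are benign/malignant (or
    +/-1).  Variances are floored at ``variance_floor`` so degenerate
    (constant) training decisions stay usable.
    """
    from .classify import encode_labels

    D = np.atleast_2d(np.asarray(decision_pairs, dtype=float))
    y = encode_labels(labels)
    if D.shape[0] != len(y):
        raise DataError("decision matrix and labels disagree in length")
    if not np.isfinite(D).all():
        raise ValueError("decision values must be finite")
    priors = np.empty(2)
    means = np.empty((2, D.shape[1]))
    variances = np.empty((2, D.shape[1]))
    covariances = np.empty((2, D.shape[1], D.shape[1]))
    for row, cls in enumerate(_CLASSES):
        sel = y == cls
        if sel.sum() < 2:
            raise DataError(
                f"class {cls:+d} has {int(sel.sum())} training decisions; need >= 2"
            )
        priors[row] = sel.mean()
        means[row] = D[sel].mean(axis=0)
        variances[row] = np.maximum(D[sel].var(axis=0), variance_floor)
        cov = np.cov(D[sel].T, bias=True).reshape(D.shape[1], D.shape[1])
        covariances[row] = cov + variance_floor * np.eye(D.shape[1])
    if variant not in ("naive", "full"):
        raise ValueError(f"unknown fusion variant {variant!r}")
    return FusionModel(priors, means, variances, variant,
                       covariances if variant == "full" else None)


def _log_scores(model: FusionModel, d: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior per class for one decision vector."""
    scores = np.log(model.priors)
    if model.variant == "full":
        for row in range(2):
            cov = model.covariances[row]
            diff = d - model.means[row]
            _, logdet = np.linalg.slogdet(cov)
            scores[row] += -0.5 * (
                len(d) * np.log(2 * np.pi) + logdet
                + diff @ np.linalg.solve(cov, diff)
            )
        return scores
    for row in range(2):
        mu, var = model.means[row], model.variances[row]
        scores[row] += np.sum(
            -0.5 * np.log(2 * np.pi * var) - 0.5 * (d - mu) ** 2 / var
        )
    return scores


def fuse(model: FusionModel, d1: float, d2: float | None = None, *,
         case_id: str = "", arm: str = "fused") -> TumorDecision:
    """Fuse per-arm posterior malignant likelihoods into a tumor decision.

    Accepts either ``fuse(model, d1, d2)`` for the standard two-arm case or
    ``fuse(model, vector)`` with an L-vector.  The posterior of the winning
    class is the normalized class score; an exact tie predicts benign.
    """
    if d2 is None:
        d = np.asarray(d1, dtype=float).ravel()
    else:
        d = np.array([d1, d2], dtype=float)
    if d.shape != (model.n_arms,):
        raise ValueError(f"expected {model.n_arms} decision values, got {d.shape}")
    if not np.isfinite(d).all():
        raise ValueError("decision values must be finite")
    log_scores = _log_scores(model, d)
    log_post = log_scores - logsumexp(log_scores)
    p_benign, p_malignant = np.exp(log_post)
    if log_scores[1] > log_scores[0]:  # strict: ties go to benign
        return TumorDecision(case_id, arm, "malignant", float(p_malignant),
                             score_malignant=float(p_malignant))
    return TumorDecision(case_id, arm, "benign", float(p_benign),
                         score_malignant=float(p_malignant))
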