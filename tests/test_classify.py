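import numpy as np
import pandas as pd
import pytest

from busfusion.classify import (
    ROIDecision,
    Standardizer,
    TrainedClassifier,
    classify_rois,
    classify_tumor,
    encode_labels,
    grid_search_svm,
    svm_cv_error,
    train_svm_platt,
    vote_tumor,
)
from busfusion.errors import DataError


def _separable(n=40, gap=6.0, rng=None):
    rng = rng or np.random.default_rng(0)
    X = np.vstack([
        rng.normal(-gap / 2, 0.5, size=(n // 2, 2)),
        rng.normal(gap / 2, 0.5, size=(n // 2, 2)),
    ])
    y = np.array(["benign"] * (n // 2) + ["malignant"] * (n // 2))
    return X, y


class TestGridSearch:
    def test_separable_data_reaches_perfect_cv_accuracy(self):
        X, y = _separable()
        sigma, C = grid_search_svm(X, y, sigma_grid=[2, 10, 50], C_grid=[2, 10, 50])
        assert svm_cv_error(X, y, sigma, C) == 0.0

    def test_single_point_grid_returned(self):
        X, y = _separable()
        assert grid_search_svm(X, y, sigma_grid=[7], C_grid=[13]) == (7.0, 13.0)

    def test_tie_break_prefers_small_C_then_small_sigma(self):
        X, y = _separable()  # every grid point is perfect -> smallest wins
        sigma, C = grid_search_svm(X, y, sigma_grid=[9, 3], C_grid=[20, 5])
        assert (sigma, C) == (3.0, 5.0)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(DataError):
            grid_search_svm(X, np.array(["benign"] * 10))


class TestPlattCalibration:
    def test_probability_monotone_in_margin(self):
        X, y = _separable()
        clf = train_svm_platt(X, y, sigma=3, C=10)
        margins = np.linspace(-3, 3, 20)
        p = 1.0 / (1.0 + np.exp(clf.platt_A * margins + clf.platt_B))
        assert (np.diff(p) > 0).all()  # higher margin => more malignant
        probs = clf.predict_proba_malignant(X)
        assert ((probs > 0) & (probs < 1)).all()

    def test_symmetric_gaussians_give_half_probability_at_midpoint(self):
        ps = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(-1.5, 1.0, size=(60, 1)),
                           rng.normal(1.5, 1.0, size=(60, 1))])
            y = np.array(["benign"] * 60 + ["malignant"] * 60)
            clf = train_svm_platt(X, y, sigma=3, C=10, seed=seed)
            ps.append(float(clf.predict_proba_malignant(np.array([[0.0]]))[0]))
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_duplicating_separable_training_set_keeps_boundary(self):
        X, y = _separable(gap=8.0)
        clf1 = train_svm_platt(X, y, sigma=3, C=50)
        clf2 = train_svm_platt(np.vstack([X, X]), np.concatenate([y, y]),
                               sigma=3, C=50)
        grid = np.random.default_rng(0).normal(size=(50, 2)) * 4
        np.testing.assert_allclose(clf1.margins(grid), clf2.margins(grid),
                                   atol=1e-6)


class TestLeakageGuard:
    def test_cv_error_standardizes_inside_training_folds(self):
        """svm_cv_error must match a manual loop that fits the scaler on the
        training fold only."""
        rng = np.random.default_rng(3)
        X, y = _separable(n=60, gap=2.0, rng=rng)
        X[:, 1] *= 1000.0  # wildly different scales make leakage visible
        got = svm_cv_error(X, y, sigma=4, C=10, n_folds=5, seed=7)

        from sklearn.model_selection import StratifiedKFold
        from sklearn.svm import SVC

        yi = encode_labels(y)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=7)
        errs = []
        for tr, te in cv.split(X, yi):
            mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
            clf = SVC(C=10, gamma=1.0 / (2 * 16.0))
            clf.fit((X[tr] - mu) / sd, yi[tr])
            errs.append(np.mean(clf.predict((X[te] - mu) / sd) != yi[te]))
        assert got == pytest.approx(np.mean(errs))


class TestVoting:
    def _dec(self, flags, ps):
        return [
            ROIDecision(0, i, "malignant" if f else "benign", p)
            for i, (f, p) in enumerate(zip(flags, ps))
        ]

    def test_three_of_five_malignant(self):
        d = self._dec([1, 1, 1, 0, 0], [0.9, 0.8, 0.7, 0.4, 0.3])
        out = vote_tumor(d, "c")
        assert out.predicted == "malignant"
        assert out.posterior == pytest.approx((0.9 + 0.8 + 0.7) / 3)
        assert out.vote_fraction_malignant == pytest.approx(0.6)

    def test_exact_tie_is_benign(self):
        d = self._dec([1, 1, 0, 0], [0.9, 0.9, 0.2, 0.2])
        assert vote_tumor(d, "c").predicted == "benign"

    def test_unanimous_benign_posterior(self):
        d = self._dec([0, 0, 0], [0.1, 0.1, 0.1])
        out = vote_tumor(d, "c")
        assert out.predicted == "benign"
        assert out.posterior == pytest.approx(0.9)

    def test_empty_decision_list_rejected(self):
        with pytest.raises(DataError):
            vote_tumor([], "c")

    def test_flipping_benign_to_malignant_is_monotone(self, rng):
        """A benign->malignant flip can never turn a malignant call benign."""
        for _ in range(50):
            n = int(rng.integers(1, 10))
            flags = rng.integers(0, 2, n).astype(bool)
            ps = np.where(flags, rng.uniform(0.5, 1, n), rng.uniform(0, 0.5, n))
            before = vote_tumor(self._dec(flags, ps), "c").predicted
            if not flags.all():
                i = int(np.nonzero(~flags)[0][0])
                flags2 = flags.copy()
                flags2[i] = True
                ps2 = ps.copy()
                ps2[i] = 0.8
                after = vote_tumor(self._dec(flags2, ps2), "c").predicted
                assert not (before == "malignant" and after == "benign")


class TestDecisions:
    def test_roi_decisions_independent_of_order(self):
        X, y = _separable()
        clf = train_svm_platt(pd.DataFrame(X, columns=["u", "v"]), y, 3, 10)
        table = pd.DataFrame(np.random.default_rng(1).normal(size=(8, 2)),
                             columns=["u", "v"])
        table["row0"] = range(8)
        table["col0"] = 0
        d1 = classify_rois(clf, table)
        d2 = classify_rois(clf, table.iloc[::-1])
        assert {(d.row0, d.predicted, d.p_malignant) for d in d1} == \
               {(d.row0, d.predicted, d.p_malignant) for d in d2}

    def test_missing_feature_column_rejected(self):
        X, y = _separable()
        clf = train_svm_platt(pd.DataFrame(X, columns=["u", "v"]), y, 3, 10)
        with pytest.raises(DataError):
            classify_rois(clf, pd.DataFrame({"u": [0.0]}))

    def test_tumor_decision_consistency(self):
        X, y = _separable()
        clf = train_svm_platt(pd.DataFrame(X, columns=["u", "v"]), y, 3, 10)
        vec = pd.Series({"u": 3.0, "v": 3.0})
        out = classify_tumor(clf, vec, "c", arm="morphology")
        assert out.predicted == "malignant"
        assert out.posterior >= 0.5
        assert out.p_malignant == pytest.approx(out.posterior)

    def test_save_load_roundtrip(self, tmp_path):
        X, y = _separable()
        clf = train_svm_platt(pd.DataFrame(X, columns=["u", "v"]), y, 3, 10)
        clf.save(tmp_path / "model.json")
        back = TrainedClassifier.load(tmp_path / "model.json")
        grid = np.random.default_rng(2).normal(size=(20, 2)) * 3
        np.testing.assert_allclose(clf.predict_proba_malignant(grid),
                                   back.predict_proba_malignant(grid), atol=1e-9)
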