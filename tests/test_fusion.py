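import numpy as np
import pytest
from scipy.stats import norm

from busfusion.errors import DataError
from busfusion.fusion import FusionModel, fit_fusion, fuse


def _symmetric_model(var=0.01):
    return FusionModel(
        priors=np.array([0.5, 0.5]),
        means=np.array([[0.1, 0.1], [0.9, 0.9]]),  # row 0 = benign
        variances=np.full((2, 2), var),
    )


class TestFitFusion:
    def test_label_indicator_decisions_reproduce_labels(self):
        y = np.array(["benign"] * 10 + ["malignant"] * 10)
        d = (y == "malignant").astype(float)
        D = np.column_stack([d, d]) + np.random.default_rng(0).normal(
            scale=1e-3, size=(20, 2))
        model = fit_fusion(D, y)
        pred = [fuse(model, *row).predicted for row in D]
        assert list(pred) == list(y)

    def test_balanced_priors(self):
        y = np.array(["benign"] * 8 + ["malignant"] * 8)
        D = np.random.default_rng(1).uniform(size=(16, 2))
        model = fit_fusion(D, y)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        n = 500
        y = np.array(["benign"] * (n // 2) + ["malignant"] * (n // 2))
        mu_true = {"benign": (0.2, 0.3), "malignant": (0.8, 0.7)}
        sd_true = 0.1
        D = np.vstack([
            rng.normal(mu_true[label], sd_true, size=2) for label in y
        ])
        model = fit_fusion(D, y)
        se = sd_true / np.sqrt(n // 2)
        for row, label in enumerate(("benign", "malignant")):
            for i in range(2):
                assert abs(model.means[row, i] - mu_true[label][i]) < 3 * se

    def test_class_with_single_sample_rejected(self):
        y = np.array(["benign"] * 5 + ["malignant"])
        with pytest.raises(DataError):
            fit_fusion(np.zeros((6, 2)), y)


class TestFuse:
    def test_agreeing_strong_evidence(self):
        out = fuse(_symmetric_model(), 0.9, 0.9)
        assert out.predicted == "malignant"
        assert out.posterior > 0.99

    def test_conflicting_evidence_ties_to_benign(self):
        out = fuse(_symmetric_model(), 0.9, 0.1)
        assert out.posterior == pytest.approx(0.5, abs=1e-9)
        assert out.predicted == "benign"

    def test_matches_hand_computed_bayes_rule(self):
        """Direct recomputation of prior x Gaussian-product, normalized."""
        model = FusionModel(
            priors=np.array([0.6, 0.4]),
            means=np.array([[0.25, 0.35], [0.75, 0.8]]),
            variances=np.array([[0.04, 0.02], [0.01, 0.03]]),
        )
        rng = np.random.default_rng(7)
        for d1, d2 in rng.uniform(size=(10, 2)):
            num_b = 0.6 * norm.pdf(d1, 0.25, 0.2) * norm.pdf(d2, 0.35, np.sqrt(0.02))
            num_m = 0.4 * norm.pdf(d1, 0.75, 0.1) * norm.pdf(d2, 0.8, np.sqrt(0.03))
            expect_m = num_m / (num_b + num_m)
            out = fuse(model, d1, d2)
            got_m = out.posterior if out.predicted == "malignant" else 1 - out.posterior
            assert got_m == pytest.approx(expect_m, abs=1e-10)
            assert out.predicted == ("malignant" if num_m > num_b else "benign")

    def test_uninformative_arm_defers_to_other_arm(self):
        """If one arm's class-conditionals coincide, fusion equals the other
        arm's Gaussian-NB decision (cross-checked against sklearn)."""
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(5)
        n = 100
        y = np.array(["benign"] * (n // 2) + ["malignant"] * (n // 2))
        d_inf = np.where(y == "malignant",
                         rng.normal(0.8, 0.1, n), rng.normal(0.2, 0.1, n))
        model = FusionModel(
            priors=np.array([0.5, 0.5]),
            means=np.array([[0.2, 0.5], [0.8, 0.5]]),
            variances=np.array([[0.01, 0.04], [0.01, 0.04]]),
        )
        gnb = GaussianNB()
        gnb.classes_ = np.array([-1, 1])
        gnb.class_prior_ = np.array([0.5, 0.5])
        gnb.theta_ = np.array([[0.2], [0.8]])
        gnb.var_ = np.array([[0.01], [0.01]])
        pred_sklearn = gnb.predict(d_inf.reshape(-1, 1))
        for di, ps in zip(d_inf, pred_sklearn):
            out = fuse(model, di, 0.77)  # second arm value is irrelevant
            assert out.predicted == ("malignant" if ps > 0 else "benign")

    def test_log_domain_never_underflows(self):
        out = fuse(_symmetric_model(var=1e-6), 60.0, 60.0)
        assert out.predicted == "malignant"
        assert np.isfinite(out.posterior)
        assert 0.0 <= out.posterior <= 1.0

    def test_posterior_normalized_over_classes(self, rng):
        model = _symmetric_model(var=0.05)
        for d1, d2 in rng.uniform(size=(20, 2)):
            out = fuse(model, d1, d2)
            p_win = out.posterior
            assert 0.0 <= p_win <= 1.0
            assert out.posterior >= 0.5 - 1e-12  # winner's share of 2 classes

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            fuse(_symmetric_model(), np.nan, 0.5)
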