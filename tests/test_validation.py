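"""ROC/DeLong, composite models, calibration, decision curves, optimism, CV."""

import numpy as np
import pandas as pd
import pytest

from immunebalance import (
    CohortError,
    auc_score,
    bootstrap_optimism,
    calibration,
    decision_curve,
    fit_composite_model,
    logistic_spec,
    permutation_importance,
    repeated_cv,
    roc_auc,
)


def concordance_oracle(scores, labels):
    """Brute-force pairwise concordance with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_worked_example(self):
        assert roc_auc([3, 5, 1, 4], [1, 1, 0, 0]).auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = roc_auc([10, 11, 12, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert r.auc == 1.0
        assert r.youden_sensitivity == 1.0 and r.youden_specificity == 1.0

    def test_null_scores(self):
        rng = np.random.default_rng(0)
        r = roc_auc(rng.normal(size=1000), rng.integers(0, 2, 1000))
        assert r.auc == pytest.approx(0.5, abs=0.05)
        assert r.ci_low < 0.5 < r.ci_high

    def test_against_concordance_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(4, 31))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert auc_score(scores, labels) == pytest.approx(
                concordance_oracle(scores, labels), abs=1e-12
            )

    def test_youden_matches_exhaustive_argmax(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            r = roc_auc(scores, labels)
            best = max(
                (scores[labels == 1] >= t).mean() + (scores[labels == 0] < t).mean() - 1
                for t in np.concatenate([np.unique(scores), [np.inf]])
            )
            j = r.youden_sensitivity + r.youden_specificity - 1
            assert j == pytest.approx(best, abs=1e-12)

    def test_delong_ci_covers_truth(self):
        # large-sample CI should be near the asymptotic normal band
        rng = np.random.default_rng(3)
        cover = 0
        for i in range(50):
            scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
            labels = np.array([1] * 40 + [0] * 40)
            r = roc_auc(scores, labels)
            true_auc = 0.7602  # Phi(1/sqrt(2))
            cover += r.ci_low <= true_auc <= r.ci_high
        assert cover >= 40  # ~95% nominal coverage

    def test_one_class_rejected(self):
        with pytest.raises(CohortError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCompositeModel:
    def _toy_three_class(self, n=30, seed=4):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(c, 0.2, (n, 4)) for c in (0.0, 5.0, 10.0)])
        y = np.repeat(["mild", "moderate", "severe"], n)
        feats = pd.DataFrame(X, columns=["pro_mean", "anti_mean", "ids", "delta_ids"])
        return feats, pd.Series(y)

    @pytest.mark.parametrize("kind", ["ovr_logistic", "random_forest"])
    def test_separable_training_accuracy(self, kind):
        X, y = self._toy_three_class()
        model = fit_composite_model(X, y, kind=kind, seed=0)
        assert (model.predict(X) == y.to_numpy()).mean() == 1.0

    @pytest.mark.parametrize("kind", ["ovr_logistic", "random_forest"])
    def test_probability_rows_sum_to_one(self, kind):
        X, y = self._toy_three_class()
        probs = fit_composite_model(X, y, kind=kind, seed=0).predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_permuted_labels_cv_near_chance(self):
        rng = np.random.default_rng(5)
        X, y = self._toy_three_class(n=20)
        y_perm = pd.Series(rng.permutation(y.to_numpy()))

        def spec(Xa, ya, seed):
            from sklearn.linear_model import LogisticRegression

            return LogisticRegression(max_iter=2000, random_state=seed).fit(Xa, ya)

        cv = repeated_cv(spec, X.to_numpy(), y_perm.to_numpy(), k=5, repeats=3,
                         metric="accuracy", seed=0)
        assert cv["mean"] == pytest.approx(1 / 3, abs=0.12)

    def test_degenerate_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(CohortError):
            fit_composite_model(X, pd.Series(["a", "a", "a", "a", "b"]))


class TestPermutationImportance:
    def test_predictive_feature_dominates_noise(self):
        rng = np.random.default_rng(6)
        n = 120
        signal = np.repeat([0.0, 4.0], n // 2)
        X = pd.DataFrame({"signal": signal + rng.normal(0, 0.3, n),
                          "noise": rng.normal(size=n)})
        y = pd.Series(np.repeat(["lo", "hi"], n // 2))
        model = fit_composite_model(X, y, kind="ovr_logistic", seed=0)
        imp = permutation_importance(model, X, y, n_perm=30, seed=1)
        assert imp.index[0] == "signal"
        assert imp["noise"] == pytest.approx(0.0, abs=0.05)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = pd.Series(np.repeat([0, 1], 30))
        model = fit_composite_model(X, y.astype(str), seed=0)
        i1 = permutation_importance(model, X, y.astype(str), n_perm=25, seed=5)
        i2 = permutation_importance(model, X, y.astype(str), n_perm=25, seed=5)
        pd.testing.assert_series_equal(i1, i2)


class TestCalibration:
    def test_calibrated_predictions_recover_identity(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.05, 0.95, 5000)
        y = (rng.random(5000) < p).astype(int)
        cal = calibration(p, y)
        assert cal.slope == pytest.approx(1.0, abs=0.1)
        assert cal.intercept == pytest.approx(0.0, abs=0.1)

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.1, 0.9, 97)
        y = rng.integers(0, 2, 97)
        cal = calibration(p, y)
        assert cal.bins["n"].max() - cal.bins["n"].min() <= 1
        assert cal.bins["n"].sum() == 97

    def test_constant_predictions_flagged(self):
        cal = calibration(np.full(50, 0.4), np.random.default_rng(0).integers(0, 2, 50))
        assert cal.slope is None and cal.flagged

    def test_boundary_predictions_clipped(self):
        p = np.array([0.0, 0.2, 0.8, 1.0])
        cal = calibration(p, np.array([0, 0, 1, 1]))
        assert ((cal.bins["mean_predicted"] > 0) & (cal.bins["mean_predicted"] < 1)).all()


class TestDecisionCurve:
    def test_closed_form_example(self):
        # 100 samples, TP=30, FP=20 at p_t = 0.2 -> NB = 0.30 - 0.20*0.25 = 0.25
        p = np.r_[np.full(30, 0.9), np.full(20, 0.9), np.full(50, 0.01)]
        y = np.r_[np.ones(30), np.zeros(20), np.zeros(50)]
        nb = decision_curve(p, y, [0.2])
        assert nb.model[0] == pytest.approx(0.25)

    def test_random_contingency_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            p = rng.uniform(0.01, 0.99, n)
            y = rng.integers(0, 2, n)
            t = float(rng.uniform(0.05, 0.95))
            nb = decision_curve(p, y, [t])
            tp = ((p >= t) & (y == 1)).sum()
            fp = ((p >= t) & (y == 0)).sum()
            assert nb.model[0] == pytest.approx(tp / n - (fp / n) * t / (1 - t))

    def test_treat_none_identically_zero(self):
        nb = decision_curve([0.2, 0.8], [0, 1], np.linspace(0.1, 0.9, 9))
        assert (nb.treat_none == 0).all()

    def test_threshold_below_min_prediction_equals_treat_all(self):
        p = np.array([0.5, 0.6, 0.7, 0.9])
        y = np.array([0, 1, 1, 1])
        nb = decision_curve(p, y, [0.3])
        assert nb.model[0] == pytest.approx(nb.treat_all[0])

    def test_empty_grid_rejected(self):
        with pytest.raises(CohortError):
            decision_curve([0.5], [1], [])


class TestInternalValidation:
    def test_corrected_equals_apparent_minus_optimism(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + rng.normal(0, 1, 60) > 0).astype(int)
        rep = bootstrap_optimism(logistic_spec, X, y, metric="auc", B=200, seed=0)
        assert rep.corrected == pytest.approx(rep.apparent - rep.optimism, abs=1e-12)
        assert rep.n_boot + rep.n_failed == 200

    def test_null_data_corrected_auc_near_half(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 4))
        y = np.repeat([0, 1], 30)
        rep = bootstrap_optimism(logistic_spec, X, y, metric="auc", B=200, seed=1)
        assert rep.corrected == pytest.approx(0.5, abs=0.07)

    def test_constant_model_zero_optimism(self):
        class Constant:
            classes_ = np.array([0, 1])

            def predict_proba(self, X):
                return np.tile([0.5, 0.5], (len(X), 1))

        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 2))
        y = np.repeat([0, 1], 25)
        rep = bootstrap_optimism(lambda *a: Constant(), X, y, metric="auc", B=200, seed=2)
        assert rep.optimism == pytest.approx(0.0, abs=1e-12)

    def test_optimism_correction_removes_overfitting_bias(self):
        """A model fit to 4 noise features at n=40 looks better than chance
        apparently; the correction must remove at least half of that bias
        (averaged over 20 null simulations, true AUC = 0.5)."""
        rng = np.random.default_rng(14)
        apparent, corrected = [], []
        for i in range(20):
            X = rng.normal(size=(40, 4))
            y = np.repeat([0, 1], 20)
            rep = bootstrap_optimism(logistic_spec, X, y, metric="auc", B=200, seed=i)
            apparent.append(rep.apparent)
            corrected.append(rep.corrected)
        gap = np.mean(apparent) - 0.5
        removed = np.mean(apparent) - np.mean(corrected)
        assert gap > 0.05  # the scenario is genuinely optimistic
        assert removed >= 0.5 * gap

    def test_repeated_cv_separable_and_deterministic(self):
        X = np.vstack([np.zeros((20, 2)), np.ones((20, 2)) * 5])
        y = np.repeat([0, 1], 20)
        cv1 = repeated_cv(logistic_spec, X, y, k=5, repeats=2, metric="accuracy", seed=3)
        cv2 = repeated_cv(logistic_spec, X, y, k=5, repeats=2, metric="accuracy", seed=3)
        assert cv1["mean"] == 1.0
        np.testing.assert_array_equal(cv1["values"], cv2["values"])

    def test_repeated_cv_null_centered(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(100, 4))
        y = np.repeat([0, 1], 50)
        cv = repeated_cv(logistic_spec, X, y, k=10, repeats=3, metric="auc", seed=4)
        assert cv["mean"] == pytest.approx(0.5, abs=0.1)

    def test_fold_reduction_and_infeasibility(self):
        X = np.random.default_rng(16).normal(size=(12, 2))
        y = np.array([0] * 9 + [1] * 3)
        cv = repeated_cv(logistic_spec, X, y, k=10, repeats=1, metric="auc", seed=0)
        assert cv["k"] == 3
        with pytest.raises(CohortError):
            repeated_cv(logistic_spec, X, np.array([0] * 11 + [1]), k=10, repeats=1)
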