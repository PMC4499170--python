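"""ROC/AUC, naive Bayes, cross-validation, wrapper and LASSO selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import mannwhitneyu

from pulsefactor.prediction import (
    binormal_auc,
    confusion_metrics,
    cv_evaluate,
    gaussian_nb,
    l1_logistic_path,
    lasso_select,
    roc_auc,
    stratified_folds,
    wrapper_exhaustive,
)


class TestRocAuc:
    def test_four_point_example(self):
        # pairs: (0.1,0.35)+, (0.1,0.8)+, (0.4,0.35)-, (0.4,0.8)+ → 3/4
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 8, [0, 0, 0, 0, 1, 1, 1, 1]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=100, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_equals_mann_whitney(self, seed):
        """AUC == U/(n0*n1), including heavy ties."""
        rng = np.random.default_rng(seed)
        n0, n1 = rng.integers(2, 30, size=2)
        scores = np.round(rng.normal(size=n0 + n1), 1)  # force ties
        y = np.concatenate([np.zeros(n0), np.ones(n1)])
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert roc_auc(scores, y) == pytest.approx(u / (n0 * n1), abs=1e-12)


class TestBinormalAuc:
    def test_equal_means(self):
        assert binormal_auc(1.0, 0.5, 1.0, 2.0) == 0.5

    def test_left_ppi_reference_parameters(self):
        assert binormal_auc(3.101, 0.667, 3.666, 0.864) == pytest.approx(0.698, abs=1e-3)

    def test_right_ppi_reference_parameters(self):
        assert binormal_auc(3.142, 0.693, 3.979, 0.992) == pytest.approx(0.755, abs=1e-3)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            binormal_auc(0.0, 0.0, 1.0, 1.0)


class TestGaussianNB:
    def test_posterior_midpoint_symmetry(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 1, 500),
                            np.random.default_rng(1).normal(2, 1, 500)])
        y = np.repeat([0.0, 1.0], 500)
        clf = gaussian_nb(x, y)
        # force exact symmetric parameters via the fitted model
        clf.theta_ = np.array([[0.0], [2.0]])
        clf.var_ = np.array([[1.0], [1.0]])
        clf.class_prior_ = np.array([0.5, 0.5])
        assert clf.predict_proba([[1.0]])[0, 1] == pytest.approx(0.5, abs=1e-9)
        # posterior at the case mean: 1/(1+e^{-2})
        assert clf.predict_proba([[2.0]])[0, 1] == pytest.approx(0.8808, abs=1e-3)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 2))
        y = (x[:, 0] + rng.normal(0, 1, 200) > 0).astype(float)
        p1 = gaussian_nb(x, y).predict_proba(x)[:, 1]
        p2 = gaussian_nb(10 * x, y).predict_proba(10 * x)[:, 1]
        np.testing.assert_allclose(p1, p2, atol=1e-9)


class TestConfusionMetrics:
    def test_perfect(self):
        m = confusion_metrics([0, 0, 1, 1], [0, 0, 1, 1])
        for cls in ("normotensive", "hypertensive"):
            assert m[cls].sensitivity == 1.0
            assert m[cls].fpr == 0.0
            assert m[cls].precision == 1.0
            assert m[cls].f_measure == 1.0

    def test_stated_counts(self):
        # minority class: TP=5 FN=5 FP=2 TN=38
        true = np.concatenate([np.ones(10), np.zeros(40)])
        pred = np.concatenate([np.ones(5), np.zeros(5), np.ones(2), np.zeros(38)])
        m = confusion_metrics(pred, true)["hypertensive"]
        assert m.sensitivity == pytest.approx(0.5)
        assert m.fpr == pytest.approx(0.05)
        assert m.precision == pytest.approx(5 / 7)
        assert m.f_measure == pytest.approx(2 * (5 / 7) * 0.5 / (5 / 7 + 0.5))

    def test_all_majority_flags_precision(self):
        true = np.concatenate([np.ones(5), np.zeros(45)])
        pred = np.zeros(50)
        m = confusion_metrics(pred, true)["hypertensive"]
        assert m.sensitivity == 0.0
        assert m.precision == 0.0
        assert m.precision_undefined


class TestStratifiedCV:
    def test_fold_class_balance(self, small_cohort):
        y = (small_cohort.label == "hypertensive").to_numpy(dtype=float)
        folds = stratified_folds(y, k=5, seed=0)
        global_ratio = y.mean()
        for i in range(5):
            share = y[folds == i]
            # each fold's positive count within 1 subject of proportionality
            assert abs(share.sum() - global_ratio * len(share)) <= 1.0

    def test_deterministic_under_seed(self, small_cohort):
        x = small_cohort.R_PPI.to_numpy()
        y = small_cohort.label.to_numpy()
        r1 = cv_evaluate(x, y, model="nb", seed=7)
        r2 = cv_evaluate(x, y, model="nb", seed=7)
        assert r1.auc == r2.auc
        np.testing.assert_array_equal(r1.folds, r2.folds)

    def test_shuffled_labels_null_auc(self, small_cohort):
        rng = np.random.default_rng(0)
        x = small_cohort.R_PPI.to_numpy()
        y0 = (small_cohort.label == "hypertensive").to_numpy(float)
        aucs = [
            cv_evaluate(x, rng.permutation(y0), model="lr", seed=s).auc
            for s in range(10)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_minority_smaller_than_k_errors(self):
        y = np.array([0] * 20 + [1] * 3, dtype=float)
        with pytest.raises(ValueError):
            stratified_folds(y, k=5)

    def test_cv_tracks_binormal_oracle(self):
        """Single-factor CV-AUC converges to the closed-form binormal AUC."""
        mu0, s0, mu1, s1 = 0.0, 1.0, 1.2, 1.3
        target = binormal_auc(mu0, s0, mu1, s1)
        rng = np.random.default_rng(5)
        aucs = []
        for rep in range(30):
            x = np.concatenate([rng.normal(mu0, s0, 300), rng.normal(mu1, s1, 60)])
            y = np.repeat([0.0, 1.0], [300, 60])
            aucs.append(cv_evaluate(x, y, model="lr", seed=rep).auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert np.mean(aucs) == pytest.approx(target, abs=3 * se + 0.01)


def brute_force_subset_scan(X, y, model, folds):
    """Independent exhaustive scan: reversed enumeration, explicit sort key."""
    names = list(X.columns)
    best_key, best = None, None
    for r in range(len(names), 0, -1):
        for subset in itertools.combinations(names[::-1], r):
            subset = tuple(sorted(subset, key=names.index))
            auc = cv_evaluate(
                X[list(subset)].to_numpy(), y, model=model, folds=folds
            ).auc
            key = (-auc, len(subset), tuple(names.index(n) for n in subset))
            if best_key is None or key < best_key:
                best_key, best = key, (subset, auc)
    return best


class TestWrapper:
    def _toy(self, n=200, p=4, seed=0, informative=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)]
        )
        eta = -1.2 + 1.5 * X.iloc[:, informative]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return X, y

    @pytest.mark.parametrize("p", [3, 5])
    def test_matches_brute_force(self, p):
        X, y = self._toy(n=150, p=p, seed=1)
        folds = stratified_folds(y, k=5, seed=3)
        res = wrapper_exhaustive(X, y, model="lr", k=5, seed=3)
        subset, auc = brute_force_subset_scan(X, y, "lr", folds)
        assert res.selected == subset
        assert res.criterion == pytest.approx(auc, abs=1e-12)
        assert res.search_size == 2**p - 1

    def test_criterion_at_least_singletons(self):
        X, y = self._toy(n=250, p=4, seed=2)
        res = wrapper_exhaustive(X, y, model="nb", seed=0)
        assert res.criterion >= max(res.singleton_criteria.values())

    def test_duplicated_feature_tie_goes_to_singleton(self):
        X, y = self._toy(n=300, p=1, seed=4)
        X = X.rename(columns={"f0": "f1a"})
        X["f1b"] = X["f1a"]
        res = wrapper_exhaustive(X, y, model="lr", seed=1)
        assert len(res.selected) == 1

    def test_informative_feature_always_selected(self):
        """With one signal and two noise features, the signal feature is
        always kept and the chosen subset stays small (noise features can
        enter by CV luck, but never replace the signal)."""
        sizes = []
        for rep in range(20):
            X, y = self._toy(n=600, p=3, seed=200 + rep)
            res = wrapper_exhaustive(X, y, model="lr", seed=rep)
            assert "f0" in res.selected
            sizes.append(len(res.selected))
        assert np.median(sizes) <= 2


def penalized_nll(params, X, y, lam):
    b0, b = params[0], params[1:]
    eta = b0 + X @ b
    return -np.sum(y * eta - np.log1p(np.exp(eta))) + lam * np.abs(b).sum()


class TestLasso:
    def _toy(self, n=400, seed=0, rho=0.0, p=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        if rho:
            X[:, 1] = rho * X[:, 0] + np.sqrt(1 - rho**2) * X[:, 1]
        eta = -1.0 + 1.2 * X[:, 0] + (1.0 * X[:, 1] if rho else 0.0)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y

    def test_huge_penalty_triggers_fallback(self, caplog):
        X, y = self._toy(seed=1)
        res = lasso_select(X, y, lambdas=np.array([1e6, 1e5, 20.0, 5.0]), seed=0)
        assert len(res.selected) >= 1

    def test_zero_penalty_matches_unpenalized(self):
        X, y = self._toy(seed=2)
        from pulsefactor.association import fit_logistic

        coef_ref, _, _, _ = fit_logistic(X.to_numpy(), y)
        coef_l1 = l1_logistic_path(X.to_numpy(), y, lam=0.0)
        np.testing.assert_allclose(coef_l1, coef_ref[1:], atol=1e-4)

    def test_matches_generic_convex_optimizer(self):
        """saga L1 path equals a scipy BFGS-on-smoothed-|.| solution."""
        X, y = self._toy(n=300, seed=3)
        lam = 8.0
        ours = l1_logistic_path(X.to_numpy(), y, lam)

        # generic solver on the same objective (smooth |b| approximation
        # refined twice)
        x0 = np.zeros(X.shape[1] + 1)
        for eps in (1e-6, 1e-9):
            def smooth(params):
                b0, b = params[0], params[1:]
                eta = b0 + X.to_numpy() @ b
                return (
                    -np.sum(y * eta - np.log1p(np.exp(eta)))
                    + lam * np.sum(np.sqrt(b**2 + eps))
                )
            x0 = minimize(smooth, x0, method="L-BFGS-B").x
        np.testing.assert_allclose(ours, x0[1:], atol=1e-4)

    def test_correlated_pair_recovery(self):
        """With ρ=0.95 twins + 8 noise features, the penalty always keeps
        at least one twin; the minimum-CV-deviance penalty is known to be
        liberal, so noise features may enter but the set stays a proper
        subset."""
        pair_hits = 0
        for rep in range(15):
            X, y = self._toy(n=800, seed=300 + rep, rho=0.95, p=10)
            lmax = np.abs(X.to_numpy().T @ (y - y.mean())).max()
            lams = np.logspace(np.log10(lmax), np.log10(lmax) - 3, 15)
            res = lasso_select(X, y, lambdas=lams, seed=rep)
            pair_hits += bool({"f0", "f1"} & set(res.selected))
            assert len(res.selected) < X.shape[1]
        assert pair_hits >= 14  # ≥90% with binomial slack

    def test_selection_reported_with_criterion(self):
        X, y = self._toy(n=300, seed=5)
        res = lasso_select(X, y, seed=0)
        assert res.method == "lasso_lr"
        assert res.search_size == 50
        assert res.criterion > 0
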