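"""Predictive power of pulse-wave factors for hypertension.

Gaussian naive Bayes and (unpenalized) logistic regression classifiers
evaluated by stratified 5-fold cross-validation, with the pooled
out-of-fold AUC as the primary criterion; per-class sensitivity,
false-positive rate, precision and F-measure at posterior threshold 0.5;
exhaustive wrapper feature selection; and L1-penalized logistic
selection with an unpenalized refit on the selected factors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB

from .association import _binary_labels
from .params import FACTOR_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "roc_auc",
    "gaussian_nb",
    "cv_evaluate",
    "confusion_metrics",
    "wrapper_exhaustive",
    "lasso_select",
    "binormal_auc",
    "PredictionResult",
    "SelectionResult",
    "PredictionAnalysis",
]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; ties count half).

    Equivalent to the Mann-Whitney U statistic divided by n0*n1.
    """
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute an AUC")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def binormal_auc(mu0: float, sigma0: float, mu1: float, sigma1: float) -> float:
    """Closed-form AUC when both class scores are Gaussian.

    AUC = Phi((mu1 - mu0) / sqrt(sigma0^2 + sigma1^2)).
    """
    if sigma0 <= 0 or sigma1 <= 0:
        raise ValueError("class standard deviations must be positive")
    return float(norm.cdf((mu1 - mu0) / np.hypot(sigma0, sigma1)))


def gaussian_nb(X, y) -> GaussianNB:
    """Fit a Gaussian naive Bayes classifier (priors = class frequencies).

    Per-class feature variances are floored at 1e-9 times the largest
    feature variance to keep degenerate features finite (logged when it
    binds).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _binary_labels(y)
    clf = GaussianNB(var_smoothing=1e-9)
    clf.fit(X, y)
    if np.any(clf.var_ <= 1.01 * clf.epsilon_):
        logger.warning("near-zero class-conditional variance floored")
    return clf


def _make_classifier(model: str):
    model = model.lower()
    if model == "nb":
        return GaussianNB(var_smoothing=1e-9)
    if model == "lr":
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    raise ValueError(f"unknown model {model!r} (expected 'nb' or 'lr')")


@dataclass
class ClassMetrics:
    sensitivity: float
    fpr: float
    precision: float
    f_measure: float
    precision_undefined: bool = False


@dataclass
class PredictionResult:
    """Cross-validated performance of one model on one feature subset."""

    model: str
    auc: float
    per_class: dict[str, ClassMetrics]
    folds: np.ndarray
    seed: int
    features: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            f"Model {self.model.upper()}  features={list(self.features) or 'all'}  "
            f"pooled CV-AUC = {self.auc:.3f}",
            f"{'Status':<14}{'Sensitivity':>12}{'1-Spec':>8}{'Precision':>11}{'F-measure':>11}",
        ]
        for cls, m in self.per_class.items():
            lines.append(
                f"{cls:<14}{m.sensitivity:>12.3f}{m.fpr:>8.3f}"
                f"{m.precision:>11.3f}{m.f_measure:>11.3f}"
            )
        return "\n".join(lines)


@dataclass
class SelectionResult:
    """Outcome of a feature-selection run."""

    method: str
    selected: tuple[str, ...]
    criterion: float
    search_size: int
    singleton_criteria: dict[str, float] = field(default_factory=dict)


def confusion_metrics(predicted, true) -> dict[str, ClassMetrics]:
    """One-vs-rest confusion metrics per class at fixed predictions.

    Precision with no positive predictions is reported as 0 and flagged.
    """
    pred = _binary_labels(predicted)
    y = _binary_labels(true)
    out: dict[str, ClassMetrics] = {}
    for cls_val, cls_name in ((0.0, "normotensive"), (1.0, "hypertensive")):
        tp = float(np.sum((pred == cls_val) & (y == cls_val)))
        fn = float(np.sum((pred != cls_val) & (y == cls_val)))
        fp = float(np.sum((pred == cls_val) & (y != cls_val)))
        tn = float(np.sum((pred != cls_val) & (y != cls_val)))
        sens = tp / (tp + fn) if tp + fn > 0 else 0.0
        fpr = fp / (fp + tn) if fp + tn > 0 else 0.0
        undefined = (tp + fp) == 0
        prec = 0.0 if undefined else tp / (tp + fp)
        f = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        out[cls_name] = ClassMetrics(sens, fpr, prec, f, precision_undefined=undefined)
    return out


def stratified_folds(y, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1 per sample), stratified by class."""
    y = _binary_labels(y)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < k:
        raise ValueError(f"minority class smaller than k={k}; folds would miss a class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = i
    return folds


def cv_evaluate(
    X,
    y,
    model: str = "lr",
    k: int = 5,
    seed: int = 0,
    folds: np.ndarray | None = None,
    features: tuple[str, ...] = (),
) -> PredictionResult:
    """Stratified k-fold CV: pooled out-of-fold AUC + per-class metrics.

    Out-of-fold posterior probabilities from every fold are pooled into
    a single ROC (stable with few positives); class predictions use a
    0.5 posterior threshold.  Deterministic for a fixed ``seed`` (or an
    explicit ``folds`` assignment).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _binary_labels(y)
    if len(y) < k:
        raise ValueError("need at least k samples")
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    scores = np.empty(len(y))
    for i in range(k):
        test = folds == i
        train = ~test
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {i} is missing a class")
        clf = _make_classifier(model)
        clf.fit(X[train], y[train])
        scores[test] = clf.predict_proba(X[test])[:, 1]
    auc = roc_auc(scores, y)
    per_class = confusion_metrics((scores >= 0.5).astype(float), y)
    return PredictionResult(
        model=model,
        auc=auc,
        per_class=per_class,
        folds=folds,
        seed=seed,
        features=tuple(features),
    )


def wrapper_exhaustive(
    X: pd.DataFrame,
    y,
    model: str = "lr",
    k: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Exhaustive wrapper selection: best CV-AUC over all non-empty subsets.

    Every subset is scored with the *same* stratified fold assignment;
    ties go to the smaller subset, then to lexicographic column order
    (which the size-ascending, lexicographic enumeration realises by
    keeping the first maximiser).
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"f{i}" for i in range(X.shape[1])]
    names = list(X.columns)
    if len(names) > 20:
        raise ValueError("exhaustive search limited to 20 candidate features")
    y = _binary_labels(y)
    folds = stratified_folds(y, k=k, seed=seed)
    arr = X.to_numpy(dtype=float)
    col = {n: i for i, n in enumerate(names)}

    best_auc = -np.inf
    best_subset: tuple[str, ...] = ()
    singleton: dict[str, float] = {}
    n_eval = 0
    for size in range(1, len(names) + 1):
        for subset in itertools.combinations(names, size):
            idx = [col[n] for n in subset]
            res = cv_evaluate(arr[:, idx], y, model=model, k=k, folds=folds, seed=seed)
            n_eval += 1
            if size == 1:
                singleton[subset[0]] = res.auc
            if res.auc > best_auc:
                best_auc = res.auc
                best_subset = subset
    return SelectionResult(
        method=f"wrapper_{model}",
        selected=best_subset,
        criterion=best_auc,
        search_size=n_eval,
        singleton_criteria=singleton,
    )


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    p = y.mean()
    return float(np.max(np.abs(X.T @ (y - p))))


def l1_logistic_path(X, y, lam: float) -> np.ndarray:
    """Coefficients (no intercept entry) of L1-penalized logistic regression.

    Objective: sum of negative log-likelihoods + lam * ||beta||_1, with
    an unpenalized intercept.  lam = 0 falls back to the unpenalized
    MLE.
    """
    X = np.asarray(X, dtype=float)
    y = _binary_labels(y)
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    else:
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="saga", max_iter=20000, tol=1e-8
        )
    clf.fit(X, y)
    return clf.coef_.ravel()


def lasso_select(
    X: pd.DataFrame,
    y,
    lambdas: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """L1-penalized logistic selection with CV-deviance-tuned penalty.

    The penalty weight is chosen to minimise the stratified k-fold CV
    deviance (-2 log-likelihood of out-of-fold predictions) over a
    50-point log-spaced grid from lambda_max down four decades; the
    selected set is the nonzero support of the full-data fit at that
    penalty.  If the chosen penalty zeroes everything, the largest
    penalty retaining at least one factor is used instead (logged).
    Expects standardized features.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"f{i}" for i in range(X.shape[1])]
    names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    y = _binary_labels(y)
    if lambdas is None:
        lmax = _lambda_max(arr, y)
        lambdas = np.logspace(np.log10(lmax), np.log10(lmax) - 4, 50)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    folds = stratified_folds(y, k=k, seed=seed)

    deviance = np.zeros(len(lambdas))
    eps = 1e-12
    for i in range(k):
        test = folds == i
        train = ~test
        for j, lam in enumerate(lambdas):
            if lam == 0:
                clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
            else:
                clf = LogisticRegression(
                    l1_ratio=1.0, C=1.0 / lam, solver="saga", max_iter=20000, tol=1e-6
                )
            clf.fit(arr[train], y[train])
            p = np.clip(clf.predict_proba(arr[test])[:, 1], eps, 1 - eps)
            deviance[j] += -2.0 * float(
                np.sum(y[test] * np.log(p) + (1 - y[test]) * np.log(1 - p))
            )
    best_j = int(np.argmin(deviance))
    lam = float(lambdas[best_j])
    coefs = l1_logistic_path(arr, y, lam)
    selected = tuple(n for n, c in zip(names, coefs) if abs(c) > 1e-10)
    if not selected:
        # walk down from the largest penalty until something survives
        for lam_try in lambdas:  # descending grid
            coefs = l1_logistic_path(arr, y, lam_try)
            selected = tuple(n for n, c in zip(names, coefs) if abs(c) > 1e-10)
            if selected:
                lam = float(lam_try)
                logger.warning(
                    "chosen penalty selected nothing; fell back to lambda=%.4g", lam
                )
                break
        if not selected:
            raise ValueError("no penalty on the grid retains any feature")
    return SelectionResult(
        method="lasso_lr",
        selected=selected,
        criterion=float(deviance[best_j]),
        search_size=len(lambdas),
    )


class PredictionAnalysis:
    """Prediction model over a cohort feature table (statsmodels-style).

    Parameters
    ----------
    table : per-subject feature DataFrame with a ``label`` column.
    wrist : 'L' or 'R'; candidate factors are the ten of that wrist.
    model : 'nb' or 'lr'.
    select : None (use all factors), 'wrapper' or 'lasso'.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        wrist: str = "L",
        model: str = "lr",
        select: str | None = None,
        factors=None,
        k: int = 5,
        seed: int = 0,
    ):
        self.table = table
        self.wrist = wrist
        self.model = model
        self.select = select
        self.factors = list(factors) if factors is not None else list(FACTOR_NAMES)
        self.k = k
        self.seed = seed

    def fit(self) -> tuple[PredictionResult, SelectionResult | None]:
        cols = [f"{self.wrist}_{f}" for f in self.factors]
        X = self.table[cols].copy()
        # standardize over the full sample, as in the association analysis
        X = (X - X.mean()) / X.std(ddof=1)
        y = _binary_labels(self.table["label"].to_numpy())
        sel: SelectionResult | None = None
        if self.select == "wrapper":
            sel = wrapper_exhaustive(X, y, model=self.model, k=self.k, seed=self.seed)
            use = list(sel.selected)
        elif self.select == "lasso":
            sel = lasso_select(X, y, k=self.k, seed=self.seed)
            use = list(sel.selected)
        elif self.select is None:
            use = cols
        else:
            raise ValueError("select must be None, 'wrapper' or 'lasso'")
        res = cv_evaluate(
            X[use].to_numpy(),
            y,
            model=self.model,
            k=self.k,
            seed=self.seed,
            features=tuple(use),
        )
        return res, sel
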