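"""Association of pulse-wave factors with hypertension.

Each factor is standardized over the full sample and entered in a
binary logistic regression, crude and adjusted for age and BMI; the
reported odds ratio is per one standard deviation of the factor, with
Wald 95% confidence intervals.  The hypertension label follows the
WHO/ESH-ESC rule: SBP >= 140 mmHg or DBP >= 90 mmHg.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .params import FACTOR_NAMES, FACTOR_DISPLAY

logger = logging.getLogger(__name__)

SBP_THRESHOLD = 140.0  # mmHg
DBP_THRESHOLD = 90.0  # mmHg

__all__ = [
    "label_hypertension",
    "standardize",
    "fit_logistic",
    "crude_and_adjusted_or",
    "AssociationResult",
    "AssociationAnalysis",
    "AssociationResults",
    "SeparationError",
]


class SeparationError(ValueError):
    """Perfect separation: the logistic MLE is unbounded."""


def label_hypertension(sbp, dbp):
    """Classify blood pressure: hypertensive iff SBP >= 140 or DBP >= 90.

    Accepts scalars or arrays (mmHg); returns "hypertensive" /
    "normotensive" correspondingly.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if np.any(sbp <= 0) or np.any(dbp <= 0):
        raise ValueError("blood pressures must be positive (mmHg)")
    hyper = (sbp >= SBP_THRESHOLD) | (dbp >= DBP_THRESHOLD)
    out = np.where(hyper, "hypertensive", "normotensive")
    return out.item() if out.ndim == 0 else out


def standardize(values) -> tuple[np.ndarray, tuple[float, float]]:
    """z-score a column over the full sample; returns (z, (mean, sd)).

    The sd uses the n-1 convention.  A constant column has no scale and
    raises ``ValueError``.
    """
    x = np.asarray(values, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant column")
    return (x - mean) / sd, (mean, sd)


def fit_logistic(X, y, add_intercept: bool = True):
    """Maximum-likelihood logistic regression (Newton/IRLS).

    Returns ``(coef, se, pvalues, llf)`` with the intercept first when
    ``add_intercept``.  Convergence at max coefficient change < 1e-8 or
    100 iterations; non-convergence is logged.  Perfect separation
    raises :class:`SeparationError`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + int(add_intercept):
        raise ValueError("need more observations than parameters")
    design = sm.add_constant(X, has_constant="raise") if add_intercept else X
    model = sm.Logit(y, design)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # convergence is re-checked below; separation raises
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    converged = res.mle_retvals.get("converged", True)
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    # unbounded estimates show up as huge, still-growing coefficients/SEs
    if (
        np.any(~np.isfinite(coef))
        or np.any(~np.isfinite(se))
        or np.any(np.abs(coef) > 1e3)
        or (not converged and np.any(np.abs(coef) > 50))
    ):
        raise SeparationError("perfect separation detected (unbounded estimate)")
    if not converged:
        logger.warning("logistic fit did not converge in 100 iterations")
    return coef, se, np.asarray(res.pvalues, dtype=float), float(res.llf)


@dataclass
class AssociationResult:
    """Crude and age/BMI-adjusted standardized odds ratios for one factor."""

    factor: str
    crude_or: float
    crude_ci_lo: float
    crude_ci_hi: float
    crude_p: float
    adj_or: float
    adj_ci_lo: float
    adj_ci_hi: float
    adj_p: float


def _or_ci(beta: float, se: float) -> tuple[float, float, float]:
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.96 * se)),
        float(np.exp(beta + 1.96 * se)),
    )


def crude_and_adjusted_or(factor, age, bmi, labels, name: str = "factor") -> AssociationResult:
    """Per-SD odds ratios for one factor, crude and adjusted for age+BMI.

    ``labels`` may be 0/1 or the string labels produced by
    :func:`label_hypertension` (hypertensive = 1).
    """
    y = _binary_labels(labels)
    zf, _ = standardize(factor)
    za, _ = standardize(age)
    zb, _ = standardize(bmi)

    coef, se, pvals, _ = fit_logistic(zf[:, None], y)
    c_or, c_lo, c_hi = _or_ci(coef[1], se[1])
    coef, se, pvals_a, _ = fit_logistic(np.column_stack([zf, za, zb]), y)
    a_or, a_lo, a_hi = _or_ci(coef[1], se[1])
    return AssociationResult(
        factor=name,
        crude_or=c_or,
        crude_ci_lo=c_lo,
        crude_ci_hi=c_hi,
        crude_p=float(pvals[1]),
        adj_or=a_or,
        adj_ci_lo=a_lo,
        adj_ci_hi=a_hi,
        adj_p=float(pvals_a[1]),
    )


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "hypertensive").astype(float)
    return arr.astype(float)


class AssociationAnalysis:
    """Single-factor association model over a cohort feature table.

    Built from the per-subject feature DataFrame (columns ``age``,
    ``bmi``, ``label`` and ``<wrist>_<factor>``); ``fit()`` runs the
    crude and adjusted logistic regressions for every factor of the
    requested wrist and returns an :class:`AssociationResults`.
    """

    def __init__(self, table: pd.DataFrame, wrist: str = "L", factors=None):
        if wrist not in ("L", "R"):
            raise ValueError("wrist must be 'L' or 'R'")
        self.wrist = wrist
        self.factors = list(factors) if factors is not None else list(FACTOR_NAMES)
        cols = ["age", "bmi", "label"] + [f"{wrist}_{f}" for f in self.factors]
        n_before = len(table)
        self.table = table.dropna(subset=[c for c in cols if c in table.columns])
        dropped = n_before - len(self.table)
        if dropped:
            logger.info("dropped %d rows with missing analysis columns", dropped)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, wrist: str = "L", factors=None):
        return cls(table, wrist=wrist, factors=factors)

    def fit(self) -> "AssociationResults":
        rows = []
        for f in self.factors:
            col = f"{self.wrist}_{f}"
            res = crude_and_adjusted_or(
                self.table[col].to_numpy(),
                self.table["age"].to_numpy(),
                self.table["bmi"].to_numpy(),
                self.table["label"].to_numpy(),
                name=f"{self.wrist}-{FACTOR_DISPLAY[f]}",
            )
            rows.append(res)
        return AssociationResults(rows, wrist=self.wrist)


class AssociationResults:
    """Fitted association table: one row per factor."""

    def __init__(self, rows: list[AssociationResult], wrist: str):
        self.rows = rows
        self.wrist = wrist

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows]).set_index("factor")

    def summary(self) -> str:
        lines = [
            f"Association with hypertension, wrist {self.wrist} "
            "(standardized per-SD odds ratios)",
            f"{'Variable':<18}{'crude p':>9}{'crude OR (95% CI)':>24}"
            f"{'adj p':>9}{'adj OR (95% CI)':>24}",
        ]
        for r in self.rows:
            lines.append(
                f"{r.factor:<18}"
                f"{_fmt_p(r.crude_p):>9}"
                f"{r.crude_or:>8.3f} ({r.crude_ci_lo:.3f}-{r.crude_ci_hi:.3f})"
                f"{_fmt_p(r.adj_p):>9}"
                f"{r.adj_or:>8.3f} ({r.adj_ci_lo:.3f}-{r.adj_ci_hi:.3f})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return self.summary()


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"
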