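"""Univariate logistic association: 2x2 odds ratios and IRLS logistic fits.

The closed-form cross-product odds ratio with a Woolf (log-scale Wald)
confidence interval serves as an exact oracle for the saturated single-binary-
predictor logistic model: on an all-positive 2x2 table the logistic MLE slope
equals ``ln((a*d)/(b*c))`` and the Wald CI from the inverse observed
information equals the Woolf interval ``exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._base import (
    BaseEstimator,
    DomainError,
    RankError,
    SeparationError,
    ValidationError,
    ZeroCellError,
    check_is_fitted,
)
from .cohort import Cohort

__all__ = [
    "TwoByTwo",
    "OddsRatioResult",
    "LogisticFit",
    "LogisticRegressionIRLS",
    "or_from_2x2",
    "fit_logistic",
    "univariate_or_table",
    "UnivariateRow",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome contingency table.

    a: exposed cases, b: exposed controls, c: unexposed cases,
    d: unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(
                    f"cell {name} must be a nonnegative integer, got {v!r}"
                )

    @property
    def cases(self) -> int:
        return self.a + self.c

    @property
    def controls(self) -> int:
        return self.b + self.d

    def as_array(self) -> np.ndarray:
        """Rows = exposure (exposed, unexposed), columns = outcome (case, control)."""
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def swap_rows_and_columns(self) -> "TwoByTwo":
        return TwoByTwo(a=self.d, b=self.c, c=self.b, d=self.a)

    def reverse_exposure(self) -> "TwoByTwo":
        return TwoByTwo(a=self.c, b=self.d, c=self.a, d=self.b)


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with a log-scale-symmetric Wald CI and two-sided Wald p."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coding: str
    method: str  # "cross_product" | "logistic_mle"

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round(self.odds_ratio, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def or_from_2x2(
    table: TwoByTwo, alpha: float = 0.05, haldane: bool = False
) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf CI and two-sided Wald p.

    Zero cells raise :class:`ZeroCellError` unless ``haldane=True`` applies the
    Haldane-Anscombe +0.5 correction to every cell.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    zeros = [name for name, v in zip("abcd", (a, b, c, d)) if v == 0]
    if zeros:
        if not haldane:
            raise ZeroCellError(
                f"zero cell(s) {zeros} in 2x2 table; pass haldane=True for the "
                "+0.5 continuity correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log(oratio)
    ci_low = math.exp(log_or - z * se)
    ci_high = math.exp(log_or + z * se)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        odds_ratio=oratio,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        coding="exposed=1",
        method="cross_product",
    )


@dataclass(frozen=True)
class LogisticFit:
    """Result of a maximum-likelihood logistic fit."""

    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    n_iter: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Logistic MLE via iteratively reweighted least squares (Newton-Raphson).

    ``X`` must already contain an intercept column if one is wanted.
    Coefficients start at zero; iteration stops when the max-norm of the score
    (gradient of the log-likelihood) drops below ``tol``.

    Raises
    ------
    SeparationError : any coefficient exceeds 15 on the logit scale
        (complete or quasi-complete separation).
    RankError : singular observed information matrix.
    DomainError : ``y`` single-class, or n <= p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise DomainError(f"X has {n} rows but y has {y.shape[0]}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DomainError("y is constant: logistic MLE does not exist")
    if n <= p:
        raise DomainError(f"need n > p, got n={n}, p={p}")

    def loglik(b):
        eta = X @ b
        # log(1+exp(eta)) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    beta = np.zeros(p)
    ll = loglik(beta)
    converged = False
    it = 0
    info = None
    for it in range(1, max_iter + 1):
        mu = _sigmoid(X @ beta)
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise RankError("singular information matrix in IRLS") from None
        # backtracking: plain Newton can overshoot on strong signals
        new_beta = beta + step
        new_ll = loglik(new_beta)
        n_halve = 0
        while new_ll < ll and n_halve < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = loglik(new_beta)
            n_halve += 1
        beta, ll = new_beta, new_ll
        if np.max(np.abs(beta)) > 15.0:
            raise SeparationError(
                "complete or quasi-complete separation detected "
                f"(|coefficient| > 15 on the logit scale at iteration {it})"
            )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise RankError("singular information matrix at the optimum") from None
    return LogisticFit(coef=beta, cov=cov, converged=converged, n_iter=it)


class LogisticRegressionIRLS(BaseEstimator):
    """Unpenalized logistic regression classifier (IRLS / Newton-Raphson).

    sklearn-style estimator with Wald inference attributes. Unlike
    ``sklearn.linear_model.LogisticRegression`` there is no regularization, so
    fitted odds ratios are maximum-likelihood.

    Attributes (after fit): ``coef_``, ``intercept_``, ``cov_``,
    ``converged_``, ``n_iter_``, ``classes_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, fit_intercept: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.fit_intercept = fit_intercept

    def fit(self, X, y) -> "LogisticRegressionIRLS":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        res = fit_logistic(design, y, tol=self.tol, max_iter=self.max_iter)
        if self.fit_intercept:
            self.intercept_ = float(res.coef[0])
            self.coef_ = res.coef[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = res.coef.copy()
        self.cov_ = res.cov
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


_DEFAULT_CODINGS = {
    "sex": ("female=1 (male reference)", lambda s: (s == "female").astype(float)),
}

_CONTINUOUS_UNITS = {
    "age_years": "per year",
    "qrs_ms": "per ms",
    "qtc_ms": "per ms",
    "qt_ms": "per ms",
}


@dataclass(frozen=True)
class UnivariateRow:
    """One row of the univariate odds-ratio table."""

    variable: str
    result: Optional[OddsRatioResult]
    n_used: int
    error: Optional[str] = None


def univariate_or_table(
    cohort: Cohort, predictors: Sequence[str]
) -> list[UnivariateRow]:
    """One single-predictor logistic fit (with intercept) per variable.

    Binary predictors are coded 0/1 (sex: female=1, male reference, matching
    the reported direction); continuous predictors are per unit (per year,
    per ms). ``pvs_positive`` restricts to subjects with PVS performed.
    Separation or rank failures yield a flagged row instead of estimates.
    Accepts a :class:`~brsrisk.cohort.Cohort` or an equivalent DataFrame.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    rows: list[UnivariateRow] = []
    for var in predictors:
        if var not in df.columns:
            raise DomainError(f"unknown predictor {var!r}")
        sub = df[[var, "vtvf"]].dropna()
        if var in _DEFAULT_CODINGS:
            coding_desc, coder = _DEFAULT_CODINGS[var]
            x = coder(sub[var])
        elif var in _CONTINUOUS_UNITS:
            coding_desc = _CONTINUOUS_UNITS[var]
            x = sub[var].astype(float)
        else:
            coding_desc = f"{var}=1"
            x = sub[var].astype(float)
        y = sub["vtvf"].astype(float).to_numpy()
        xv = x.to_numpy(dtype=float)
        n_used = len(sub)
        if n_used < len(df):
            logger.info(
                "univariate_or_table: %s uses %d of %d records "
                "(missing values excluded)",
                var,
                n_used,
                len(df),
            )
        try:
            fit = fit_logistic(np.column_stack([np.ones(n_used), xv]), y)
            slope = fit.coef[1]
            se = fit.se()[1]
            z = stats.norm.ppf(0.975)
            result = OddsRatioResult(
                odds_ratio=math.exp(slope),
                ci_low=math.exp(slope - z * se),
                ci_high=math.exp(slope + z * se),
                p_value=float(2 * stats.norm.sf(abs(slope) / se)),
                coding=coding_desc,
                method="logistic_mle",
            )
            rows.append(UnivariateRow(variable=var, result=result, n_used=n_used))
        except (SeparationError, RankError, DomainError) as exc:
            rows.append(
                UnivariateRow(variable=var, result=None, n_used=n_used, error=str(exc))
            )
    return rows
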