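"""Firth-penalized logistic regression.

Maximum penalized likelihood with the Jeffreys-prior penalty
``l*(beta) = l(beta) + 0.5 log det I(beta)``, which removes the first-order
small-sample bias of the logistic MLE and yields finite coefficients under
complete separation.  Fitting uses Newton iteration on the modified score

    U*(beta) = X' (y - p + h * (0.5 - p)),

where ``h`` are the diagonals of the weighted hat matrix, with step-halving
whenever a step would decrease the penalized likelihood.

Two surfaces are provided: :class:`FirthLogisticRegression`, a
scikit-learn style estimator (``fit`` / ``predict_proba`` /
``get_params``), and thin functions (:func:`fit_firth`,
:func:`penalized_lrt`, :func:`wald_ci`, :func:`profile_penalized_ci`,
:func:`vif`) over named design matrices for the analysis pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cohort import CohortTable, complete_cases

logger = logging.getLogger(__name__)

INTERCEPT = "(Intercept)"

# convergence constants: fixed, documented defaults
TOL_SCORE = 1e-6
TOL_STEP = 1e-8
MAX_ITER = 100
STEP_HALVING = 0.5
MAX_HALVINGS = 30


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Numeric model matrix with an intercept column and named terms.

    ``terms`` maps each model variable to the indices of its columns
    (one for binary/continuous, one per non-reference level for
    categorical variables).
    """

    X: np.ndarray
    columns: tuple[str, ...]
    terms: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix shape")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def without(self, variables) -> "DesignMatrix":
        """Sub-design dropping every column of the given variables."""
        drop = set()
        for v in variables:
            if v not in self.terms:
                raise KeyError(f"variable {v!r} not in design")
            drop.update(self.terms[v])
        keep = [j for j in range(len(self.columns)) if j not in drop]
        remap = {old: new for new, old in enumerate(keep)}
        terms = {
            v: tuple(remap[j] for j in idx)
            for v, idx in self.terms.items()
            if v not in variables
        }
        return DesignMatrix(
            self.X[:, keep], tuple(self.columns[j] for j in keep), terms
        )


def design_matrix(table: CohortTable, variables) -> DesignMatrix:
    """Build an intercept-plus-covariates design from a cohort table.

    Categorical variables are expanded to reference-coded indicators
    against their declared reference level.  Rows must be complete on the
    requested variables.
    """
    variables = list(variables)
    cols = [np.ones(table.n)]
    names = [INTERCEPT]
    terms: dict[str, tuple[int, ...]] = {}
    for v in variables:
        s = table.spec(v)
        if s.kind == "categorical":
            raw = table.data[v]
            if raw.isna().any():
                raise ValueError(f"design requires complete cases; {v!r} has missing values")
            idx = []
            for level in s.levels:
                if level == s.reference_level:
                    continue
                idx.append(len(names))
                names.append(f"{v}[{level}]")
                cols.append((raw == level).to_numpy(dtype=float))
            terms[v] = tuple(idx)
        else:
            vals = table.column(v)
            if np.isnan(vals).any():
                raise ValueError(f"design requires complete cases; {v!r} has missing values")
            terms[v] = (len(names),)
            names.append(v)
            cols.append(vals.astype(float))
    X = np.column_stack(cols) if cols else np.empty((table.n, 0))
    return DesignMatrix(X, tuple(names), terms)


# ---------------------------------------------------------------------------
# Core solver
# ---------------------------------------------------------------------------

def _penalized_parts(X: np.ndarray, y: np.ndarray, beta: np.ndarray):
    """Penalized log-likelihood, fitted probabilities, information, hat diag."""
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    w = p * (1.0 - p)
    XW = X * w[:, None]
    info = X.T @ XW
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf, p, info, np.zeros(len(y))
    # h_i = w_i * x_i' I^{-1} x_i
    solved = np.linalg.solve(info, X.T)
    h = w * np.einsum("ij,ji->i", X, solved)
    return ll + 0.5 * logdet, p, info, h


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    free: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    tol_score: float = TOL_SCORE,
    tol_step: float = TOL_STEP,
):
    """Newton iteration on the modified score; ``free`` masks profiled fits."""
    n, q = X.shape
    if free is None:
        free = np.ones(q, dtype=bool)
    beta = np.zeros(q) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll, p, info, h = _penalized_parts(X, y, beta)
    if not np.isfinite(ll):
        raise np.linalg.LinAlgError("information matrix singular at start")
    converged = False
    score_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        score = X.T @ (y - p + h * (0.5 - p))
        score_norm = float(np.max(np.abs(score[free]))) if free.any() else 0.0
        if score_norm <= tol_score:
            converged = True
            break
        sub = np.ix_(free, free)
        delta = np.zeros(q)
        delta[free] = np.linalg.solve(info[sub], score[free])
        step = 1.0
        slack = 1e-10 * max(1.0, abs(ll))  # float rounding near the optimum
        for _ in range(MAX_HALVINGS):
            cand = beta + step * delta
            ll_new, p_new, info_new, h_new = _penalized_parts(X, y, cand)
            if ll_new >= ll - slack:
                break
            step *= STEP_HALVING
        beta, ll, p, info, h = cand, ll_new, p_new, info_new, h_new
        if float(np.max(np.abs(step * delta))) <= tol_step:
            score = X.T @ (y - p + h * (0.5 - p))
            score_norm = float(np.max(np.abs(score[free]))) if free.any() else 0.0
            converged = score_norm <= tol_score
            break
    else:
        score = X.T @ (y - p + h * (0.5 - p))
        score_norm = float(np.max(np.abs(score[free]))) if free.any() else 0.0
        converged = score_norm <= tol_score
    if not converged:
        logger.warning(
            "Firth fit did not converge in %d iterations (score %.3g)",
            it, score_norm,
        )
    return {
        "beta": beta, "loglik_pen": ll, "info": info, "hat": h,
        "iterations": it, "converged": converged, "score_norm": score_norm,
        "prob": p,
    }


# ---------------------------------------------------------------------------
# Named-fit surface
# ---------------------------------------------------------------------------

@dataclass
class FirthFit:
    """A fitted Firth-penalized logistic model."""

    beta: np.ndarray
    names: tuple[str, ...]
    cov: np.ndarray
    loglik_pen: float
    hat: np.ndarray
    iterations: int
    converged: bool
    score_norm: float
    terms: dict[str, tuple[int, ...]]
    n: int
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    outcome: str | None = None
    variables: tuple[str, ...] | None = None

    def coef(self, term: str) -> float:
        return float(self.beta[self._index(term)])

    def _index(self, term: str) -> int:
        if term in self.names:
            return self.names.index(term)
        if term in self.terms and len(self.terms[term]) == 1:
            return self.terms[term][0]
        raise KeyError(f"unknown term {term!r}")

    def linear_predictor(self, X: np.ndarray | None = None) -> np.ndarray:
        return (self.X if X is None else X) @ self.beta


def fit_firth(design: DesignMatrix, y, **options) -> FirthFit:
    """Fit a Firth-penalized logistic regression on a named design.

    Raises on rank-deficient designs and non-binary outcomes.  An
    iteration-cap exit returns a fit flagged ``converged=False`` (with a
    logged warning), never a silent result.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != design.n:
        raise ValueError("outcome vector does not align with the design rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1 with no missing values")
    q = design.X.shape[1]
    if np.linalg.matrix_rank(design.X) < q:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; drop aliased columns explicitly"
        )
    res = _firth_newton(design.X, y, **options)
    cov = np.linalg.inv(res["info"])
    return FirthFit(
        beta=res["beta"], names=design.columns, cov=cov,
        loglik_pen=res["loglik_pen"], hat=res["hat"],
        iterations=res["iterations"], converged=res["converged"],
        score_norm=res["score_norm"], terms=dict(design.terms),
        n=design.n, X=design.X, y=y,
    )


def fit_model(table: CohortTable, outcome: str, variables, **options) -> FirthFit:
    """Complete-case Firth fit of ``outcome`` on ``variables`` from a table."""
    variables = list(variables)
    sub = complete_cases(table, [outcome] + variables)
    design = design_matrix(sub, variables)
    fit = fit_firth(design, sub.column(outcome), **options)
    fit.outcome = outcome
    fit.variables = tuple(variables)
    return fit


def penalized_lrt(full: FirthFit, reduced: FirthFit) -> float:
    """Penalized likelihood-ratio p-value for nested Firth fits.

    The null penalized log-likelihood is the full model profiled with the
    dropped coefficients constrained to zero, keeping the full model's
    Jeffreys penalty — the convention of reference Firth implementations.
    Comparing each model at its own optimum instead would leave a
    dimension-dependent ``0.5 log det I`` remainder in the statistic and
    makes the test anticonservative.  The statistic is referred to a
    chi-square with df equal to the column difference.
    """
    if not set(reduced.names) <= set(full.names):
        raise ValueError("models are not nested (reduced columns not in full)")
    if full.n != reduced.n:
        raise ValueError("models were fitted on different row sets")
    df = len(full.names) - len(reduced.names)
    if df == 0:
        return 1.0
    free = np.array([name in reduced.names for name in full.names])
    beta0 = full.beta.copy()
    beta0[~free] = 0.0
    prof = _firth_newton(full.X, full.y, free=free, beta0=beta0)
    stat = max(0.0, 2.0 * (full.loglik_pen - prof["loglik_pen"]))
    return float(chi2.sf(stat, df))


@dataclass(frozen=True)
class EffectEstimate:
    """An odds ratio with its confidence interval and test p-value."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    ci_method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("interval must bracket the odds ratio")


def wald_ci(fit: FirthFit, term: str, level: float = 0.95) -> EffectEstimate:
    """Wald odds-ratio interval ``exp(beta ± z·se)`` for one term."""
    j = fit._index(term)
    b = fit.beta[j]
    se = float(np.sqrt(fit.cov[j, j]))
    z = norm.ppf(0.5 + level / 2.0)
    p = 2.0 * float(norm.sf(abs(b) / se)) if se > 0 else float("nan")
    return EffectEstimate(
        term=fit.names[j], odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)), ci_high=float(np.exp(b + z * se)),
        p_value=p, n_used=fit.n, ci_method="wald",
    )


def _profile_loglik(fit: FirthFit, j: int, value: float) -> float:
    q = len(fit.beta)
    free = np.ones(q, dtype=bool)
    free[j] = False
    beta0 = fit.beta.copy()
    beta0[j] = value
    res = _firth_newton(fit.X, fit.y, free=free, beta0=beta0)
    return res["loglik_pen"]


def term_lrt_p(fit: FirthFit, term: str) -> float:
    """Penalized-likelihood-ratio p-value for a single column being zero."""
    j = fit._index(term)
    stat = max(0.0, 2.0 * (fit.loglik_pen - _profile_loglik(fit, j, 0.0)))
    return float(chi2.sf(stat, 1))


def profile_penalized_ci(
    fit: FirthFit, term: str, level: float = 0.95
) -> EffectEstimate:
    """Profile penalized-likelihood interval for one term's odds ratio.

    Endpoints are the points where twice the drop in profiled penalized
    log-likelihood reaches the chi-square(1) quantile; found by bracketed
    root search on each side of the estimate.  The p-value is the
    penalized LRT of the term at zero, so the test and interval are dual.
    """
    if not fit.converged:
        raise ValueError("profile interval requires a converged fit")
    j = fit._index(term)
    bhat = float(fit.beta[j])
    lmax = fit.loglik_pen
    crit = chi2.ppf(level, 1) / 2.0

    def g(b: float) -> float:
        return (lmax - _profile_loglik(fit, j, b)) - crit

    se = max(float(np.sqrt(fit.cov[j, j])), 1e-3)

    def find(side: int) -> float:
        step = se
        lo = bhat
        while step <= 64 * se:
            hi = bhat + side * step
            if abs(hi) > 10.0 and g(hi) < 0:
                raise ValueError(
                    f"profile bound for {term!r} not bracketed within ±10 log-odds"
                )
            if g(hi) >= 0:
                a, b = sorted((lo, hi))
                return float(brentq(g, a, b, xtol=1e-8))
            lo = hi
            step *= 2.0
        raise ValueError(
            f"profile bound for {term!r} not bracketed within ±10 log-odds"
        )

    low, high = find(-1), find(+1)
    return EffectEstimate(
        term=fit.names[j], odds_ratio=float(np.exp(bhat)),
        ci_low=float(np.exp(low)), ci_high=float(np.exp(high)),
        p_value=term_lrt_p(fit, term), n_used=fit.n, ci_method="profile",
    )


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------

def vif(design: DesignMatrix) -> pd.Series:
    """Variance inflation factors for every non-intercept column.

    Each column is regressed on the remaining non-intercept columns plus
    an intercept; VIF_j = 1/(1 - R²_j).  Perfectly collinear or constant
    columns report ``inf``.
    """
    idx = [j for j, c in enumerate(design.columns) if c != INTERCEPT]
    if len(idx) < 2:
        raise ValueError("VIF needs at least two non-intercept columns")
    out = {}
    for j in idx:
        yj = design.X[:, j]
        others = [k for k in idx if k != j]
        Z = np.column_stack([np.ones(design.n), design.X[:, others]])
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0.0:
            out[design.columns[j]] = float("inf")
            continue
        coef, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
        ssr = float(np.sum((yj - Z @ coef) ** 2))
        r2 = 1.0 - ssr / sst
        out[design.columns[j]] = (
            float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        )
    return pd.Series(out, name="VIF")


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class FirthLogisticRegression(BaseEstimator, ClassifierMixin):
    """Binary logistic regression with Jeffreys-prior (Firth) penalization.

    Drop-in scikit-learn classifier: finite coefficients under complete
    separation and reduced small-sample coefficient bias relative to the
    unpenalized MLE.

    Parameters
    ----------
    fit_intercept : bool, default True
        Add an intercept column to the design.
    max_iter : int, default 100
        Newton iteration cap; exceeding it leaves ``converged_`` False.
    tol_score : float, default 1e-6
        Convergence threshold on the max absolute modified score.
    tol_step : float, default 1e-8
        Secondary stop on the max absolute coefficient update.

    Attributes
    ----------
    coef_ : ndarray of shape (1, n_features)
    intercept_ : ndarray of shape (1,)
    cov_ : ndarray
        Covariance of ``[intercept, coef]`` (inverse Fisher information).
    loglik_ : float
        Penalized log-likelihood at the optimum.
    hat_ : ndarray of shape (n_samples,)
        Hat-matrix diagonals at the optimum.
    n_iter_ : int
    converged_ : bool
    score_norm_ : float
    """

    def __init__(self, fit_intercept: bool = True, max_iter: int = MAX_ITER,
                 tol_score: float = TOL_SCORE, tol_step: float = TOL_STEP):
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_step = tol_step

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("FirthLogisticRegression requires exactly 2 classes")
        y01 = (y == self.classes_[1]).astype(float)
        Xd = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        res = _firth_newton(
            Xd, y01, max_iter=self.max_iter,
            tol_score=self.tol_score, tol_step=self.tol_step,
        )
        beta = res["beta"]
        if self.fit_intercept:
            self.intercept_ = beta[:1].copy()
            self.coef_ = beta[1:][None, :]
        else:
            self.intercept_ = np.zeros(1)
            self.coef_ = beta[None, :]
        self.cov_ = np.linalg.inv(res["info"])
        self.loglik_ = res["loglik_pen"]
        self.hat_ = res["hat"]
        self.n_iter_ = res["iterations"]
        self.converged_ = res["converged"]
        self.score_norm_ = res["score_norm"]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]
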