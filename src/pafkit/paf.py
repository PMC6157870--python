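"""Population-attributable-fraction estimators and their comparison.

Three estimators of the fraction of outcome events attributable to binary
risk factors, all sharing one fitted multivariable Firth logistic model:

* **combined / sequential PAR (Bruzzi–Coughlin chain)** — the adjusted AF
  of a factor set S evaluated from the fitted linear predictor, either by
  the Bruzzi case-load formula (``1 − mean over cases of exp(η(S→0) − η)``)
  or by g-computation (``1 − Σ p̂(η(S→0)) / Σ p̂(η)`` over all subjects);
  Coughlin's per-factor PAR is the first-removal sequential contribution.
* **average PAR** — the mean of a factor's sequential contributions over
  all k! removal orderings; computed either by explicit enumeration or by
  the Shapley-weight shortcut over 2^k subsets (the two agree to
  floating-point precision and are mutual oracles in the test suite).
* **doubly robust PAR** — an augmented inverse-probability-weighted
  estimate of E[Y with the factor removed], combining a propensity model
  and an outcome model, consistent when either is correctly specified.

No refitting between eliminations: every subset AF re-evaluates the one
fitted model's predictions with factors set to reference.  Refit-per-subset
is available via ``refit=True`` on :func:`combined_af` for sensitivity
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .cohort import CohortTable, complete_cases
from .firth import FirthFit, design_matrix, fit_firth, fit_model
from .synthetic import shapley_weight

logger = logging.getLogger(__name__)

METHODS = ("bruzzi", "gcomp")


@dataclass(frozen=True)
class AFEstimate:
    """An attributable fraction for a set of factors, with provenance."""

    factors: tuple[str, ...]
    value: float
    method: str
    model_variables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value > 1.0 + 1e-12:
            raise ValueError("attributable fraction cannot exceed 1")


@dataclass
class SequentialAFTrace:
    """Per-position AF contributions along one removal ordering."""

    ordering: tuple[str, ...]
    contributions: np.ndarray
    method: str

    @property
    def total(self) -> float:
        return float(self.contributions.sum())


@dataclass
class AveragePARTable:
    """Per-factor average (Shapley) PAR and the subset weights used."""

    values: dict[str, float]
    mode: str
    method: str
    weights: dict[int, float]  # subset size -> Shapley weight

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))


@dataclass
class DoublyRobustFit:
    """AIPW estimate of the outcome risk with one factor removed."""

    factor: str
    par: float
    ey0: float
    mean_y: float
    n: int
    n_clipped: int
    propensity_fit: FirthFit = field(repr=False, default=None)
    outcome_fit: FirthFit = field(repr=False, default=None)


@dataclass
class MethodComparison:
    """Per-factor PAR and dense rank (1 = largest) for each estimator."""

    table: pd.DataFrame  # index = factors; columns: <method>, <method>_rank

    @property
    def factors(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# Model-based (Bruzzi / g-computation) AF
# ---------------------------------------------------------------------------

def _model_frame(fit: FirthFit, table: CohortTable | None):
    """Design, outcome and factor-column map for AF evaluation."""
    if table is not None:
        if fit.variables is None or fit.outcome is None:
            raise ValueError(
                "fit carries no variable roster; fit it with fit_model() "
                "or pass table=None to use the stored design"
            )
        sub = complete_cases(table, [fit.outcome, *fit.variables])
        design = design_matrix(sub, fit.variables)
        if design.columns != fit.names:
            raise ValueError("table does not reproduce the fitted design")
        return design.X, sub.column(fit.outcome)
    return fit.X, fit.y


def _zeroed(X: np.ndarray, fit: FirthFit, S) -> np.ndarray:
    X0 = X.copy()
    for f in S:
        if f not in fit.terms:
            raise KeyError(f"factor {f!r} is not a variable of the fitted model")
        for j in fit.terms[f]:
            X0[:, j] = 0.0
    return X0


def combined_af(
    fit: FirthFit,
    table: CohortTable | None,
    S,
    method: str = "bruzzi",
    refit: bool = False,
) -> AFEstimate:
    """Adjusted attributable fraction of a factor set from a fitted model.

    ``method='bruzzi'`` (default) evaluates the case-load formula
    ``1 − (1/n₁) Σ_cases exp(η_i(S→0) − η_i)``; ``method='gcomp'``
    standardizes fitted risks over all subjects,
    ``1 − Σ_i p̂(η_i(S→0)) / Σ_i p̂(η_i)``.  With ``refit=True`` the model
    is refitted without the factors in S and its predictions replace the
    zeroed-out predictions (sensitivity analysis only).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    S = tuple(S)
    X, y = _model_frame(fit, table)
    eta = X @ fit.beta
    if not S:
        return AFEstimate(S, 0.0, method, fit.variables or ())
    if refit:
        if fit.variables is None:
            raise ValueError("refit=True requires a fit built by fit_model()")
        keep = [v for v in fit.variables if v not in S]
        sub_design_cols = [
            j for v, idx in fit.terms.items() if v not in S for j in idx
        ]
        Xr = np.column_stack([np.ones(len(y)), X[:, sub_design_cols]])
        from .firth import DesignMatrix, INTERCEPT
        names = (INTERCEPT,) + tuple(fit.names[j] for j in sub_design_cols)
        terms = {}
        pos = 1
        for v in keep:
            terms[v] = tuple(range(pos, pos + len(fit.terms[v])))
            pos += len(fit.terms[v])
        rfit = fit_firth(DesignMatrix(Xr, names, terms), y)
        eta0 = Xr @ rfit.beta
    else:
        eta0 = _zeroed(X, fit, S) @ fit.beta
    if method == "bruzzi":
        cases = y == 1.0
        value = 1.0 - float(np.mean(np.exp(eta0[cases] - eta[cases])))
    else:
        value = 1.0 - float(expit(eta0).sum() / expit(eta).sum())
    return AFEstimate(S, value, method, fit.variables or ())


def sequential_af(
    fit: FirthFit,
    table: CohortTable | None,
    ordering,
    method: str = "bruzzi",
) -> SequentialAFTrace:
    """Sequential AF contributions along one removal ordering.

    The j-th contribution is ``AF({π₁..π_j}) − AF({π₁..π_{j−1}})``; the
    contributions telescope to the combined AF of the full ordering.
    """
    ordering = tuple(ordering)
    if sorted(ordering) != sorted(set(ordering)) or set(ordering) - set(fit.terms):
        raise ValueError("ordering must be a permutation of model factors")
    contributions = []
    prev = 0.0
    for j in range(1, len(ordering) + 1):
        cur = combined_af(fit, table, ordering[:j], method=method).value
        contributions.append(cur - prev)
        prev = cur
    return SequentialAFTrace(ordering, np.asarray(contributions), method)


def coughlin_par(
    fit: FirthFit, table: CohortTable | None, factor: str, method: str = "bruzzi"
) -> AFEstimate:
    """Coughlin's per-factor PAR: the first-removal sequential contribution.

    Equals the combined AF of the single factor, evaluated with the
    multivariable model's coefficients (Bruzzi case-load formula by
    default) — the proportion of events preventable if this factor were
    eliminated first.
    """
    if factor not in fit.terms:
        raise KeyError(f"factor {factor!r} is not in the fitted model")
    return combined_af(fit, table, (factor,), method=method)


def average_par(
    fit: FirthFit,
    table: CohortTable | None,
    factors=None,
    mode: str = "shapley",
    method: str = "bruzzi",
) -> AveragePARTable:
    """Average PAR per factor over all removal orderings.

    ``mode='enumerate'`` averages sequential contributions over all k!
    orderings (k <= 10); ``mode='shapley'`` computes the identical value
    as the Shapley sum over 2^k subsets (k <= 20).  Per-factor values sum
    to the combined AF of the full factor set.
    """
    factors = tuple(factors) if factors is not None else tuple(
        fit.variables or fit.terms
    )
    k = len(factors)
    if mode == "enumerate" and k > 10:
        raise ValueError("enumerate mode caps at k=10 (k! orderings); use mode='shapley'")
    if mode == "shapley" and k > 20:
        raise ValueError("shapley mode caps at k=20 (2^k subsets); reduce the factor set")
    if mode not in ("enumerate", "shapley"):
        raise ValueError("mode must be 'enumerate' or 'shapley'")

    X, y = _model_frame(fit, table)
    eta = X @ fit.beta
    cases = y == 1.0

    cache: dict[frozenset, float] = {frozenset(): 0.0}

    def af(S: frozenset) -> float:
        if S not in cache:
            eta0 = _zeroed(X, fit, S) @ fit.beta
            if method == "bruzzi":
                cache[S] = 1.0 - float(np.mean(np.exp(eta0[cases] - eta[cases])))
            else:
                cache[S] = 1.0 - float(expit(eta0).sum() / expit(eta).sum())
        return cache[S]

    values = {f: 0.0 for f in factors}
    if mode == "enumerate":
        total = 0
        for perm in permutations(factors):
            total += 1
            removed = frozenset()
            prev = 0.0
            for f in perm:
                removed = removed | {f}
                cur = af(removed)
                values[f] += cur - prev
                prev = cur
        for f in factors:
            values[f] /= total
    else:
        for f in factors:
            others = [g for g in factors if g != f]
            acc = 0.0
            for mask in range(2 ** (k - 1)):
                S = frozenset(others[j] for j in range(k - 1) if (mask >> j) & 1)
                acc += shapley_weight(len(S), k) * (af(S | {f}) - af(S))
            values[f] = acc
    weights = {s: shapley_weight(s, k) for s in range(k)}
    return AveragePARTable(values, mode, method, weights)


# ---------------------------------------------------------------------------
# Doubly robust PAR
# ---------------------------------------------------------------------------

def doubly_robust_par(
    table: CohortTable,
    factor: str,
    outcome: str,
    confounders,
    clip: float = 0.01,
    propensity_confounders=None,
    outcome_confounders=None,
) -> DoublyRobustFit:
    """Doubly robust (AIPW) PAR of one binary factor.

    Fits a Firth logistic propensity model P(A=1 | C) and a Firth logistic
    outcome model P(Y=1 | A, C) on the complete cases, then estimates the
    counterfactual risk with the factor removed as

        Ê[Y(0)] = mean( m̂(0,C) + (1−A)·(Y − m̂(0,C)) / (1−π̂(C)) )

    and PAR = 1 − Ê[Y(0)] / mean(Y).  ``1−π̂`` is floored at ``clip``
    (clips are counted and logged); positivity failure — every
    observation clipped — is an error.  The estimate is consistent when
    either the propensity or the outcome model is correct; the optional
    ``propensity_confounders`` / ``outcome_confounders`` overrides let
    each nuisance model use its own covariate set (misspecification and
    sensitivity analyses).
    """
    confounders = list(confounders)
    prop_vars = list(propensity_confounders) if propensity_confounders is not None else confounders
    out_vars = list(outcome_confounders) if outcome_confounders is not None else confounders
    all_vars = list(dict.fromkeys(confounders + prop_vars + out_vars))
    sub = complete_cases(table, [outcome, factor] + all_vars)
    if sub.spec(factor).kind != "binary":
        raise ValueError(f"factor {factor!r} must be binary")
    a = sub.column(factor)
    y = sub.column(outcome)

    prop_fit = fit_model(sub, factor, prop_vars)
    pi = expit(design_matrix(sub, prop_vars).X @ prop_fit.beta)

    out_fit = fit_model(sub, outcome, [factor] + out_vars)
    X_out = design_matrix(sub, [factor] + out_vars).X
    X0 = X_out.copy()
    X0[:, out_fit.terms[factor][0]] = 0.0
    m0 = expit(X0 @ out_fit.beta)

    denom = 1.0 - pi
    clipped = denom < clip
    n_clipped = int(clipped.sum())
    if n_clipped == len(denom):
        raise ValueError(
            f"positivity violated: every 1−π̂ below the clip floor {clip}"
        )
    if n_clipped:
        logger.info("doubly robust PAR for %s: clipped %d propensities", factor, n_clipped)
    denom = np.maximum(denom, clip)

    ey0 = float(np.mean(m0 + (1.0 - a) * (y - m0) / denom))
    ey0_clamped = min(max(ey0, 0.0), 1.0)
    if ey0_clamped != ey0:
        logger.warning("AIPW E[Y(0)] %.4f truncated into [0, 1]", ey0)
    mean_y = float(y.mean())
    return DoublyRobustFit(
        factor=factor, par=1.0 - ey0_clamped / mean_y, ey0=ey0_clamped,
        mean_y=mean_y, n=sub.n, n_clipped=n_clipped,
        propensity_fit=prop_fit, outcome_fit=out_fit,
    )


# ---------------------------------------------------------------------------
# Comparison and uncertainty
# ---------------------------------------------------------------------------

def _dense_ranks(values: np.ndarray) -> np.ndarray:
    return rankdata(-values, method="dense").astype(int)


def compare_methods(
    fit: FirthFit,
    table: CohortTable,
    af_method: str = "bruzzi",
    clip: float = 0.01,
) -> MethodComparison:
    """Per-factor PAR under all three estimators, with per-method ranks.

    Columns: average PAR (Shapley), doubly robust PAR (confounders =
    remaining factors), Coughlin first-removal PAR; ranks are dense with
    1 the largest value.
    """
    if fit.variables is None or fit.outcome is None:
        raise ValueError("compare_methods needs a fit built by fit_model()")
    factors = list(fit.variables)
    avg = average_par(fit, table, factors, mode="shapley", method=af_method)
    rows = {}
    for f in factors:
        dr = doubly_robust_par(
            table, f, fit.outcome, [g for g in factors if g != f], clip=clip
        )
        rows[f] = {
            "average": avg.values[f],
            "doubly_robust": dr.par,
            "coughlin": coughlin_par(fit, table, f, method=af_method).value,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index").loc[factors]
    for col in ("average", "doubly_robust", "coughlin"):
        frame[f"{col}_rank"] = _dense_ranks(frame[col].to_numpy())
    return MethodComparison(frame)


def bootstrap_par(
    table: CohortTable,
    outcome: str,
    factors,
    B: int = 200,
    seed: int = 0,
    af_method: str = "bruzzi",
    level: float = 0.95,
) -> pd.DataFrame:
    """Nonparametric bootstrap percentile intervals for the three PARs.

    Resamples patients with replacement, refits the multivariable model
    and recomputes every estimator per replicate.  Replicates where a fit
    fails are dropped (counted in the ``failed`` attribute of the result).
    """
    factors = list(factors)
    rng = np.random.default_rng(seed)
    stats: dict[tuple[str, str], list[float]] = {}
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, table.n, size=table.n)
        boot = table.with_rows(pd.Index(idx))
        try:
            fit = fit_model(boot, outcome, factors)
            comp = compare_methods(fit, boot, af_method=af_method)
        except (ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        for f in factors:
            for m in ("average", "doubly_robust", "coughlin"):
                stats.setdefault((f, m), []).append(comp.table.loc[f, m])
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    rows = []
    for (f, m), vals in stats.items():
        v = np.asarray(vals)
        rows.append({
            "factor": f, "method": m, "n_boot": len(v),
            "ci_low": float(np.percentile(v, lo)),
            "ci_high": float(np.percentile(v, hi)),
        })
    out = pd.DataFrame(rows)
    out.attrs["failed"] = failed
    return out
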