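"""Variable screening and backward elimination for the outcome model.

The selection chain mirrors common epidemiological practice: univariable
Firth-penalized fits per candidate, a liberal screening threshold
(default p < 0.1) to form the multivariable candidate set, then backward
elimination at a stricter stay level (default 0.05) with categorical
variables entering and leaving as whole indicator blocks, plus a
variance-inflation-factor collinearity check on the final design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, complete_cases
from .firth import (
    EffectEstimate,
    FirthFit,
    design_matrix,
    fit_firth,
    penalized_lrt,
    profile_penalized_ci,
    vif,
    wald_ci,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenEntry:
    """Univariable result for one candidate variable."""

    variable: str
    effects: list[EffectEstimate]
    p_overall: float
    n_used: int
    estimable: bool = True

    def selected(self, alpha: float) -> bool:
        return self.estimable and self.p_overall < alpha


@dataclass
class SelectionTrace:
    """Removal log of one backward-elimination run."""

    steps: list[tuple[int, str, float, float]]  # (step, variable, p, loglik_pen)
    final: list[str]
    n_used: int
    final_fit: FirthFit | None = field(default=None, repr=False)


class SelectionError(RuntimeError):
    """Backward elimination aborted; carries the trace accumulated so far."""

    def __init__(self, message: str, trace: SelectionTrace):
        super().__init__(message)
        self.trace = trace


def univariable_effects(
    table: CohortTable,
    variable: str,
    outcome: str,
    ci_method: str = "profile",
    compute_ci: bool = True,
    level: float = 0.95,
) -> ScreenEntry:
    """Firth logistic fit of the outcome on one variable alone.

    Complete cases on {variable, outcome}; categorical variables are
    expanded against their reference and the overall p-value is the block
    penalized LRT against the intercept-only model.  A variable with a
    single observed level is flagged inestimable.
    """
    sub = complete_cases(table, [outcome, variable])
    y = sub.column(outcome)
    spec = sub.spec(variable)
    observed = sub.data[variable].dropna()
    if observed.nunique() < 2:
        return ScreenEntry(variable, [], float("nan"), sub.n, estimable=False)
    if spec.kind == "categorical":
        present = [lv for lv in spec.levels if (observed == lv).any()]
        if spec.reference_level not in present:
            return ScreenEntry(variable, [], float("nan"), sub.n, estimable=False)
        if len(present) < len(spec.levels):
            # unobserved levels would alias their indicator columns
            from .cohort import VariableSpec
            newspec = VariableSpec(
                spec.name, "categorical", spec.role,
                tuple(present), spec.reference_level, spec.units,
            )
            sub = CohortTable(
                sub.data, tuple(newspec if s.name == variable else s for s in sub.specs),
                sub.applied_rules,
            )
    design = design_matrix(sub, [variable])
    fit = fit_firth(design, y)
    null_fit = fit_firth(design.without([variable]), y)
    p_overall = penalized_lrt(fit, null_fit)
    effects = []
    if compute_ci:
        ci = profile_penalized_ci if ci_method == "profile" else wald_ci
        for j in fit.terms[variable]:
            effects.append(ci(fit, fit.names[j], level=level))
    return ScreenEntry(variable, effects, p_overall, sub.n)


def screen(
    table: CohortTable,
    candidates,
    outcome: str,
    alpha: float = 0.1,
    entries_out: list | None = None,
) -> list[str]:
    """Candidates whose univariable penalized-LRT p is below ``alpha``.

    Returned in input order.  ``entries_out``, if given, collects the full
    :class:`ScreenEntry` list (without confidence intervals) for reporting.
    """
    selected = []
    for var in candidates:
        entry = univariable_effects(table, var, outcome, compute_ci=False)
        if entries_out is not None:
            entries_out.append(entry)
        if entry.selected(alpha):
            selected.append(var)
    return selected


def backward_select(
    table: CohortTable,
    candidates,
    outcome: str,
    alpha_stay: float = 0.05,
) -> SelectionTrace:
    """Backward elimination on a fixed complete-case base.

    The analysis rows are fixed once, on the union of all candidates plus
    the outcome, so successive models are comparable.  Each step refits
    the Firth model, computes each remaining variable's block penalized
    LRT p-value, and removes the worst variable with p >= ``alpha_stay``
    (ties broken by removing the later one in input order); it stops when
    every remaining variable has p < ``alpha_stay``.
    """
    candidates = list(candidates)
    steps: list[tuple[int, str, float, float]] = []
    if not candidates:
        return SelectionTrace(steps, [], 0)
    sub = complete_cases(table, [outcome] + candidates)
    y = sub.column(outcome)
    current = candidates[:]
    step = 0
    fit = None
    while current:
        design = design_matrix(sub, current)
        try:
            fit = fit_firth(design, y)
            if not fit.converged:
                raise RuntimeError("Firth fit did not converge")
            pvals = {}
            for var in current:
                reduced = fit_firth(design.without([var]), y)
                pvals[var] = penalized_lrt(fit, reduced)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            raise SelectionError(
                f"backward elimination aborted at step {step}: {exc}",
                SelectionTrace(steps, current, sub.n),
            ) from exc
        worst, worst_p = None, -1.0
        for var in current:  # >= keeps the later-input variable on ties
            if pvals[var] >= alpha_stay and pvals[var] >= worst_p:
                worst, worst_p = var, pvals[var]
        if worst is None:
            break
        step += 1
        steps.append((step, worst, worst_p, fit.loglik_pen))
        logger.info("step %d: removed %s (p=%.4f)", step, worst, worst_p)
        current.remove(worst)
    if current:
        design = design_matrix(sub, current)
        fit = fit_firth(design, y)
        fit.outcome = outcome
        fit.variables = tuple(current)
    else:
        fit = None
    return SelectionTrace(steps, current, sub.n, final_fit=fit)


def collinearity_check(
    table: CohortTable, variables, outcome: str | None = None, flag_above: float = 10.0
) -> pd.DataFrame:
    """Variance inflation factors on the design of ``variables``.

    Complete cases on the variables (and outcome, when given, to match
    the model's analysis rows); columns with VIF above ``flag_above`` are
    flagged.
    """
    variables = list(variables)
    if not variables:
        return pd.DataFrame(columns=["column", "VIF", "flagged"])
    base = [outcome] if outcome else []
    sub = complete_cases(table, base + variables)
    design = design_matrix(sub, variables)
    if design.X.shape[1] < 3:  # intercept + one column: VIF is vacuously 1
        col = design.columns[-1]
        return pd.DataFrame({"column": [col], "VIF": [1.0], "flagged": [False]})
    values = vif(design)
    return pd.DataFrame({
        "column": values.index,
        "VIF": values.to_numpy(),
        "flagged": values.to_numpy() > flag_above,
    })
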