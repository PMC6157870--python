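"""End-to-end orchestration: load → screen → select → dichotomize → PAR.

The pipeline reproduces a standard cohort outcome-attribution analysis:
univariable screening of candidate baseline variables, backward
elimination to a final multivariable Firth model, dichotomization of any
retained non-binary predictor, the three-estimator PAR comparison, and an
exposure-overlap tally among the poor-outcome patients.  Every stage logs
the number of analysis rows it used, because shifting complete-case
denominators are the main reproduction hazard in this kind of analysis.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    CohortTable,
    DichotomizationRule,
    VariableSpec,
    baseline_summary,
    complete_cases,
    dichotomize,
    load_cohort,
)
from .firth import fit_model, wald_ci
from .paf import MethodComparison, compare_methods
from .selection import (
    ScreenEntry,
    SelectionError,
    SelectionTrace,
    backward_select,
    collinearity_check,
    screen,
)
from .synthetic import generate, proscis_preset

logger = logging.getLogger(__name__)

#: standard cut points for predictors that need dichotomization before PAR
DEFAULT_RULES = (
    DichotomizationRule("age", 75.0, "ge", "age ≥75", name="age75"),
    DichotomizationRule("nihss", 4.0, "gt", "NIHSS >4", name="nihss4"),
    DichotomizationRule("education", 10.0, "le", "education ≤10", name="edu10"),
)


@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis bit-identically.

    ``input_path`` may be None, in which case a synthetic preset cohort of
    ``synthetic_n`` patients is generated from ``seed``.
    """

    input_path: str | None = None
    variables: list[VariableSpec] = field(default_factory=list)
    outcome: str = "poor_outcome"
    candidates: list[str] | None = None  # None = every non-outcome variable
    screening_alpha: float = 0.1
    alpha_stay: float = 0.05
    rules: list[DichotomizationRule] = field(default_factory=lambda: list(DEFAULT_RULES))
    par_methods: list[str] = field(
        default_factory=lambda: ["average", "doubly_robust", "coughlin"]
    )
    af_method: str = "bruzzi"
    bootstrap_B: int = 0
    seed: int = 0
    synthetic_n: int = 507
    output_dir: str = "pafkit_out"

    def __post_init__(self) -> None:
        for a in (self.screening_alpha, self.alpha_stay):
            if not (0.0 < a < 1.0):
                raise ValueError("alpha thresholds must lie in (0, 1)")

    # -- serialization ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "variables" in raw:
            raw["variables"] = [
                VariableSpec(
                    v["name"], v["kind"], v.get("role", "covariate"),
                    tuple(v["levels"]) if v.get("levels") else None,
                    v.get("reference_level"), v.get("units", ""),
                )
                for v in raw["variables"]
            ]
        if "rules" in raw:
            raw["rules"] = [
                DichotomizationRule(
                    r["source"], float(r["threshold"]), r["direction"],
                    r.get("exposed_label", ""), r.get("name"),
                )
                for r in raw["rules"]
            ]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    baseline: pd.DataFrame | None = None
    screening: pd.DataFrame | None = None
    selected: list[str] = field(default_factory=list)
    trace: SelectionTrace | None = None
    adjusted: pd.DataFrame | None = None
    vif_report: pd.DataFrame | None = None
    par: MethodComparison | None = None
    overlap: dict | None = None
    run_log: dict = field(default_factory=dict)
    error: str | None = None


def _load_stage(config: PipelineConfig) -> CohortTable:
    if config.input_path is not None:
        table = load_cohort(config.input_path, config.variables)
        logger.info("loaded %d rows from %s", table.n, config.input_path)
        return table
    spec = proscis_preset(seed=config.seed)
    table = generate(spec, config.synthetic_n)
    logger.info("generated synthetic preset cohort, n=%d", table.n)
    return table


def _screening_frame(entries: list[ScreenEntry], alpha: float) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "variable": e.variable,
            "p_value": e.p_overall,
            "n_used": e.n_used,
            "estimable": e.estimable,
            "selected": e.selected(alpha),
        }
        for e in entries
    ])


def _par_variable(config: PipelineConfig, table: CohortTable, var: str) -> str | None:
    """Map a selected model variable to its binary stand-in for PAR."""
    if table.spec(var).kind == "binary":
        return var
    for rule in config.rules:
        if rule.source == var:
            return rule.name
    return None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; identical configs give identical bundles.

    Stage order: load/generate, dichotomize, baseline summary,
    univariable screening, backward elimination, adjusted ORs and VIF on
    the final model, PAR comparison on the (dichotomized) final factors,
    exposure overlap among cases.  A stage failure returns the partial
    bundle with ``error`` set.
    """
    bundle = ReportBundle()
    bundle.run_log = {
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": sys.version.split()[0],
    }
    try:
        table = _load_stage(config)
        applicable = [r for r in config.rules
                      if r.source in table.names and r.name not in table.names]
        table = dichotomize(table, applicable)
        bundle.run_log["n_loaded"] = table.n
        bundle.baseline = baseline_summary(table, config.outcome)

        if config.candidates is None:
            candidates = [
                v for v in table.names
                if v != config.outcome and v not in {r.name for r in applicable}
            ]
        else:
            candidates = list(config.candidates)
        entries: list[ScreenEntry] = []
        selected = screen(
            table, candidates, config.outcome,
            alpha=config.screening_alpha, entries_out=entries,
        )
        bundle.screening = _screening_frame(entries, config.screening_alpha)
        bundle.run_log["n_candidates"] = len(candidates)
        bundle.run_log["n_screened_in"] = len(selected)
        if not selected:
            bundle.selected = []
            bundle.trace = SelectionTrace([], [], 0)
            logger.info("no variable passed screening; stopping before selection")
            return bundle

        trace = backward_select(
            table, selected, config.outcome, alpha_stay=config.alpha_stay
        )
        bundle.trace = trace
        bundle.selected = trace.final
        bundle.run_log["n_model_rows"] = trace.n_used
        if not trace.final:
            logger.info("backward elimination removed every candidate")
            return bundle

        fit = trace.final_fit
        rows = []
        for var in trace.final:
            for j in fit.terms[var]:
                est = wald_ci(fit, fit.names[j])
                rows.append({
                    "term": est.term, "odds_ratio": est.odds_ratio,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "p_value": est.p_value,
                })
        bundle.adjusted = pd.DataFrame(rows)
        bundle.vif_report = collinearity_check(
            table, trace.final, outcome=config.outcome
        )

        par_vars = []
        for var in trace.final:
            mapped = _par_variable(config, table, var)
            if mapped is None:
                logger.warning(
                    "no dichotomization rule for selected non-binary %r; "
                    "excluded from PAR estimation", var,
                )
            else:
                par_vars.append(mapped)
        if par_vars:
            par_fit = fit_model(table, config.outcome, par_vars)
            bundle.par = compare_methods(par_fit, table, af_method=config.af_method)
            bundle.overlap = exposure_overlap(table, par_vars, config.outcome)
            bundle.run_log["n_par_rows"] = par_fit.n
    except (ValueError, KeyError, SelectionError, np.linalg.LinAlgError) as exc:
        logger.error("pipeline aborted: %s", exc)
        bundle.error = str(exc)
        if isinstance(exc, SelectionError):
            bundle.trace = exc.trace
    return bundle


def exposure_overlap(table: CohortTable, predictors, outcome: str) -> dict:
    """Partition the cases by how many predictors they are exposed to.

    Among outcome-positive patients: exposed to none of the binary
    predictors, to exactly one, to two or more, or carrying a missing
    value in any predictor.  The four counts partition the cases.
    """
    predictors = list(predictors)
    for p in predictors:
        if table.spec(p).kind != "binary":
            raise ValueError(f"predictor {p!r} must be binary")
    cases = table.data[table.data[outcome] == 1.0]
    vals = cases[predictors].to_numpy(dtype=float)
    any_missing = np.isnan(vals).any(axis=1)
    n_exposed = np.nansum(vals, axis=1)
    counts = {
        "none": int(((n_exposed == 0) & ~any_missing).sum()),
        "exactly_one": int(((n_exposed == 1) & ~any_missing).sum()),
        "multiple": int(((n_exposed >= 2) & ~any_missing).sum()),
        "missing": int(any_missing.sum()),
    }
    counts["cases"] = len(cases)
    return counts


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _fmt_or(v: float) -> str:
    return f"{v:.2f}"


def _fmt_par(v: float) -> str:
    return f"{100.0 * v:.2f}%"


def _par_frame(comp: MethodComparison) -> pd.DataFrame:
    rows = []
    for f in comp.factors:
        r = comp.table.loc[f]
        rows.append({
            "factor": f,
            "average_par": _fmt_par(r["average"]),
            "average_rank": int(r["average_rank"]),
            "doubly_robust_par": _fmt_par(r["doubly_robust"]),
            "doubly_robust_rank": int(r["doubly_robust_rank"]),
            "coughlin_par": _fmt_par(r["coughlin"]),
            "coughlin_rank": int(r["coughlin_rank"]),
        })
    return pd.DataFrame(rows)


def write_report(bundle: ReportBundle, output_dir, formats=("tsv", "txt")) -> list[Path]:
    """Render the bundle as TSV tables plus a plain-text summary.

    ORs are formatted to 2 decimals and PARs as percentages with 2
    decimals.  File names are stable across runs.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame | None, columns=None):
        if "tsv" not in formats:
            return
        path = outdir / f"{name}.tsv"
        if frame is None or frame.empty:
            pd.DataFrame(columns=columns or []).to_csv(path, sep="\t", index=False)
        else:
            frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    emit("baseline", bundle.baseline, ["variable", "statistic", "yes", "no"])
    emit("screening", bundle.screening,
         ["variable", "p_value", "n_used", "estimable", "selected"])
    trace_frame = pd.DataFrame(
        bundle.trace.steps if bundle.trace else [],
        columns=["step", "removed", "p_value", "loglik_pen"],
    )
    emit("selection", trace_frame)
    adj = None
    if bundle.adjusted is not None and not bundle.adjusted.empty:
        adj = bundle.adjusted.copy()
        for c in ("odds_ratio", "ci_low", "ci_high"):
            adj[c] = adj[c].map(_fmt_or)
    emit("adjusted_or", adj, ["term", "odds_ratio", "ci_low", "ci_high", "p_value"])
    emit("vif", bundle.vif_report, ["column", "VIF", "flagged"])
    emit("par_comparison", _par_frame(bundle.par) if bundle.par else None,
         ["factor", "average_par", "average_rank", "doubly_robust_par",
          "doubly_robust_rank", "coughlin_par", "coughlin_rank"])
    if bundle.overlap is not None:
        emit("overlap", pd.DataFrame([bundle.overlap]))

    if "txt" in formats:
        path = outdir / "report.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("pafkit analysis report\n======================\n\n")
            fh.write("Run log: " + json.dumps(bundle.run_log, sort_keys=True) + "\n\n")
            if bundle.error:
                fh.write(f"PIPELINE ERROR: {bundle.error}\n\n")
            fh.write(f"Final predictors: {', '.join(bundle.selected) or '(none)'}\n\n")
            if bundle.par is not None:
                fh.write("Population attributable risk comparison\n")
                fh.write(_par_frame(bundle.par).to_string(index=False) + "\n\n")
            if bundle.overlap is not None:
                fh.write("Exposure overlap among cases: "
                         + json.dumps(bundle.overlap) + "\n")
        written.append(path)
    return written
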