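"""Cohort tables: variable metadata, I/O, dichotomization, missingness.

A :class:`CohortTable` is the single in-memory representation of
patient-level analysis data: one row per patient, one column per declared
variable, with missing values carried as NaN and every analysis stage
responsible for its own complete-case restriction (no imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINDS = ("binary", "categorical", "continuous")
ROLES = ("outcome", "exposure", "covariate")

#: strings treated as missing on input
NA_VALUES = ("", "NA")


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one cohort variable.

    Binary variables are coded 0/1 with 1 = exposed/present.  Categorical
    variables carry an ordered tuple of level labels and a declared
    reference level; they are expanded to reference-coded indicators only
    at model time, never in storage.
    """

    name: str
    kind: str
    role: str = "covariate"
    levels: tuple[str, ...] | None = None
    reference_level: str | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(f"categorical {self.name!r} needs >=2 levels")
            ref = self.reference_level
            if ref is None:
                object.__setattr__(self, "reference_level", self.levels[0])
            elif ref not in self.levels:
                raise ValueError(
                    f"reference level {ref!r} not among levels of {self.name!r}"
                )
        if self.role == "outcome" and self.kind != "binary":
            raise ValueError(f"outcome {self.name!r} must be binary")


@dataclass(frozen=True)
class DichotomizationRule:
    """Cut a numeric variable into a 0/1 exposure indicator.

    ``direction`` names the comparison that defines exposure: ``ge`` means
    exposed iff value >= threshold, and so on.  A missing source value
    yields a missing derived value.
    """

    source: str
    threshold: float
    direction: str  # one of ge, gt, le, lt
    exposed_label: str = ""
    name: str | None = None

    _OPS = {"ge": np.greater_equal, "gt": np.greater,
            "le": np.less_equal, "lt": np.less}

    def __post_init__(self) -> None:
        if self.direction not in self._OPS:
            raise ValueError(f"direction must be one of {tuple(self._OPS)}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.name is None:
            object.__setattr__(
                self, "name", f"{self.source}_{self.direction}{self.threshold:g}"
            )

    def apply(self, values: np.ndarray) -> np.ndarray:
        out = self._OPS[self.direction](values, self.threshold).astype(float)
        out[np.isnan(values)] = np.nan
        return out


@dataclass
class CohortTable:
    """Patients x variables with metadata and an explicit missingness mask.

    ``data`` holds binary/continuous columns as float (NaN = missing) and
    categorical columns as object dtype of level labels (NaN = missing).
    """

    data: pd.DataFrame
    specs: tuple[VariableSpec, ...]
    applied_rules: tuple[DichotomizationRule, ...] = field(default=())

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in specs")
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        self.data = self.data.loc[:, names].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        for s in self.specs:
            col = self.data[s.name]
            if s.kind in ("binary", "continuous"):
                vals = pd.to_numeric(col, errors="raise").astype(float)
                self.data[s.name] = vals
                if s.kind == "binary":
                    ok = vals.dropna().isin([0.0, 1.0])
                    if not ok.all():
                        bad = vals.dropna()[~ok].iloc[0]
                        raise ValueError(
                            f"binary variable {s.name!r} has value {bad!r} outside {{0,1}}"
                        )
            else:
                nonmiss = col.dropna()
                bad = ~nonmiss.astype(str).isin(s.levels)
                if bad.any():
                    row = nonmiss[bad].index[0]
                    raise ValueError(
                        f"categorical {s.name!r}: value {nonmiss[bad].iloc[0]!r} "
                        f"at row {row} not among declared levels {s.levels}"
                    )

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(f"no variable named {name!r}")

    def column(self, name: str) -> np.ndarray:
        self.spec(name)
        return self.data[name].to_numpy()

    def with_rows(self, index) -> "CohortTable":
        return CohortTable(
            self.data.loc[index].reset_index(drop=True),
            self.specs,
            self.applied_rules,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_cohort(path, specs, delimiter: str | None = None) -> CohortTable:
    """Read a delimiter-separated text file into a :class:`CohortTable`.

    Comma is the default separator; tab is accepted (``delimiter=None``
    sniffs between the two from the header line).  Blank cells and ``NA``
    are missing.  Unparseable numeric cells become missing; categorical
    values outside the declared levels raise.

    Raises
    ------
    ValueError
        If a declared column is absent from the header, or a categorical
        cell holds an undeclared level.
    """
    specs = tuple(specs)
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, na_values=list(NA_VALUES),
        keep_default_na=False, skipinitialspace=True, encoding="utf-8",
    )
    missing_cols = [s.name for s in specs if s.name not in raw.columns]
    if missing_cols:
        raise ValueError(f"input file lacks declared columns: {missing_cols}")
    data = {}
    for s in specs:
        col = raw[s.name]
        if s.kind in ("binary", "continuous"):
            data[s.name] = pd.to_numeric(col, errors="coerce").astype(float)
        else:
            data[s.name] = col.where(col.notna(), np.nan)
    return CohortTable(pd.DataFrame(data), specs)


def save_cohort(table: CohortTable, path, delimiter: str = ",") -> None:
    """Write a cohort table; missing cells become empty strings.

    Binary columns are written as integers so a save/load round trip
    preserves values and missingness exactly.
    """
    out = table.data.copy()
    for s in table.specs:
        if s.kind == "binary":
            out[s.name] = out[s.name].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
    out.to_csv(path, sep=delimiter, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def dichotomize(table: CohortTable, rules) -> CohortTable:
    """Append one binary exposure column per rule; sources are retained.

    Re-applying a rule already on the table is a no-op when the rule is
    identical and an error when a different rule claims the same name.
    """
    rules = tuple(rules)
    data = table.data.copy()
    specs = list(table.specs)
    applied = list(table.applied_rules)
    for rule in rules:
        prior = next((r for r in applied if r.name == rule.name), None)
        if prior is not None:
            if prior == rule:
                continue
            raise ValueError(f"conflicting rule already applied under name {rule.name!r}")
        if rule.name in [s.name for s in specs]:
            raise ValueError(f"variable {rule.name!r} already exists")
        src = table.spec(rule.source)
        if src.kind == "categorical":
            raise ValueError(
                f"cannot dichotomize categorical variable {rule.source!r} "
                "without numeric coding"
            )
        data[rule.name] = rule.apply(table.column(rule.source))
        specs.append(
            VariableSpec(rule.name, "binary", "exposure", units=src.units)
        )
        applied.append(rule)
    return CohortTable(data, tuple(specs), tuple(applied))


def complete_cases(table: CohortTable, variables) -> CohortTable:
    """Rows with no missing value among ``variables`` (identity if empty)."""
    variables = list(variables)
    for v in variables:
        table.spec(v)
    if not variables:
        return table
    keep = table.data[variables].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "complete cases on %s: dropped %d of %d rows",
            variables, dropped, table.n,
        )
    return table.with_rows(keep[keep].index)


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

def _fmt_count(k: int, n: int) -> str:
    pct = 100.0 * k / n if n else float("nan")
    return f"{k} ({pct:.1f}%)"


def _summary_cell(values: np.ndarray, kind: str) -> list[tuple[str, str]]:
    vals = values[~np.isnan(values)] if kind != "categorical" else values
    if kind == "binary":
        v = vals.astype(float)
        return [("", _fmt_count(int(v.sum()), v.size))]
    if kind == "continuous":
        q25, med, q75 = np.percentile(vals, [25, 50, 75]) if vals.size else (np.nan,) * 3
        mean = vals.mean() if vals.size else np.nan
        sd = vals.std(ddof=1) if vals.size > 1 else np.nan
        return [
            ("mean±sd", f"{mean:.1f}±{sd:.1f}"),
            ("median (IQR)", f"{med:g} ({q25:g}–{q75:g})"),
        ]
    raise AssertionError(kind)


def baseline_summary(table: CohortTable, group_by: str) -> pd.DataFrame:
    """Per-variable descriptive statistics split by a binary grouping column.

    Binary and categorical variables report count (percent) with the
    per-variable complete-case denominator inside each group; continuous
    variables report mean±sd and median (IQR), the IQR using the
    linear-interpolation quantile convention.
    """
    gspec = table.spec(group_by)
    if gspec.kind != "binary":
        raise ValueError(f"group_by variable {group_by!r} must be binary")
    groups = {"yes": table.column(group_by) == 1.0,
              "no": table.column(group_by) == 0.0}
    rows = []
    for s in table.specs:
        if s.name == group_by:
            continue
        if s.kind == "categorical":
            col = table.data[s.name]
            for level in s.levels:
                row = {"variable": s.name, "statistic": level}
                for gname, gmask in groups.items():
                    sub = col[gmask].dropna()
                    row[gname] = _fmt_count(int((sub == level).sum()), len(sub))
                rows.append(row)
        else:
            col = table.data[s.name].to_numpy(dtype=float)
            cells = {g: _summary_cell(col[m], s.kind) for g, m in groups.items()}
            for i, (stat, _) in enumerate(cells["yes"]):
                rows.append({
                    "variable": s.name,
                    "statistic": stat or "n (%)",
                    "yes": cells["yes"][i][1],
                    "no": cells["no"][i][1],
                })
    return pd.DataFrame(rows, columns=["variable", "statistic", "yes", "no"])
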