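import numpy as np
import pandas as pd
import pytest

from pafkit import CohortTable, VariableSpec
from pafkit.synthetic import SyntheticSpec, tilted_pmf


def counts_2x2(case_exp, case_unexp, ctrl_exp, ctrl_unexp,
               exposure="x", outcome="y") -> CohortTable:
    """Patient-level table from 2x2 cell counts."""
    y = [1.0] * (case_exp + case_unexp) + [0.0] * (ctrl_exp + ctrl_unexp)
    x = ([1.0] * case_exp + [0.0] * case_unexp
         + [1.0] * ctrl_exp + [0.0] * ctrl_unexp)
    specs = (
        VariableSpec(outcome, "binary", "outcome"),
        VariableSpec(exposure, "binary", "exposure"),
    )
    return CohortTable(pd.DataFrame({outcome: y, exposure: x}), specs)


def grouped_table(levels, case_counts, ctrl_counts,
                  variable="g", outcome="y", reference=None) -> CohortTable:
    """Patient-level table from a (levels x outcome) count table."""
    rows_g, rows_y = [], []
    for lv, a, b in zip(levels, case_counts, ctrl_counts):
        rows_g += [lv] * (a + b)
        rows_y += [1.0] * a + [0.0] * b
    specs = (
        VariableSpec(outcome, "binary", "outcome"),
        VariableSpec(variable, "categorical", "exposure",
                     tuple(levels), reference or levels[0]),
    )
    return CohortTable(pd.DataFrame({outcome: rows_y, variable: rows_g}), specs)


def half_augmented_or(case_exp, case_unexp, ctrl_exp, ctrl_unexp) -> float:
    return ((case_exp + 0.5) * (ctrl_unexp + 0.5)) / (
        (ctrl_exp + 0.5) * (case_unexp + 0.5)
    )


@pytest.fixture(scope="session")
def k3_spec() -> SyntheticSpec:
    """Three positively dependent binary factors with a logistic outcome."""
    joint = tilted_pmf([0.3, 0.2, 0.25], assoc=0.4)
    return SyntheticSpec(
        factors=("f1", "f2", "f3"),
        joint=joint,
        beta0=-2.0,
        beta=np.log([2.5, 2.0, 1.7]),
    )


@pytest.fixture(scope="session")
def k2_independent_spec() -> SyntheticSpec:
    joint = tilted_pmf([0.4, 0.25], assoc=0.0)
    return SyntheticSpec(
        factors=("a", "b"), joint=joint, beta0=-1.5, beta=np.log([2.2, 1.8])
    )
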