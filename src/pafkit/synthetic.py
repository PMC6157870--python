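"""Synthetic cohorts with known, computable attributable fractions.

The generator draws correlated binary risk factors (either from an
explicit joint probability table over all 2^k exposure profiles, or by
thresholding a latent Gaussian copula), a Bernoulli outcome from a
logistic model on those factors, and per-cell missingness.  For the
explicit-pmf variant the true attributable fraction of any factor set —
the quantity every estimator in :mod:`pafkit.paf` targets — is an exact
finite sum, which is what makes parameter-recovery testing possible
without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import CohortTable, VariableSpec

#: stream indices for counter-based seed splitting: exposures and outcome
#: come first so adding missingness (or more variables) never perturbs them
_STREAM_EXPOSURE = 0
_STREAM_OUTCOME = 1
_STREAM_MISSING_BASE = 2


@dataclass(frozen=True)
class PMFJoint:
    """Explicit joint distribution over all 2^k exposure profiles.

    Profile ``i`` encodes factor ``j`` in bit ``j`` (factor 0 is the least
    significant bit).  Admits exact truth computation.
    """

    pmf: np.ndarray

    def __post_init__(self) -> None:
        pmf = np.asarray(self.pmf, dtype=float)
        object.__setattr__(self, "pmf", pmf)
        k = int(round(math.log2(len(pmf))))
        if 2 ** k != len(pmf):
            raise ValueError("pmf length must be a power of two")
        if (pmf < 0).any():
            raise ValueError("pmf entries must be nonnegative")
        if abs(pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf must sum to 1 within 1e-12")

    @property
    def k(self) -> int:
        return int(round(math.log2(len(self.pmf))))

    def profiles(self) -> np.ndarray:
        """All 2^k profiles as a (2^k, k) 0/1 matrix."""
        idx = np.arange(len(self.pmf))
        return ((idx[:, None] >> np.arange(self.k)) & 1).astype(float)


@dataclass(frozen=True)
class GaussianCopulaJoint:
    """Correlated binaries from a thresholded latent multivariate normal.

    Factor ``j`` is 1 when its latent normal exceeds the ``1 - p_j``
    quantile, so marginal prevalences are exact while the dependence comes
    from the latent correlation matrix ``corr`` (symmetric, unit diagonal,
    positive definite).  Truths for this variant are Monte Carlo only.
    """

    prevalences: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalences, dtype=float)
        R = np.asarray(self.corr, dtype=float)
        object.__setattr__(self, "prevalences", p)
        object.__setattr__(self, "corr", R)
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("prevalences must lie strictly in (0, 1)")
        if R.shape != (len(p), len(p)):
            raise ValueError("correlation matrix shape does not match prevalences")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")

    @property
    def k(self) -> int:
        return len(self.prevalences)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a cohort with binary risk factors.

    Outcome model: ``Y ~ Bernoulli(expit(beta0 + sum_f beta_f A_f))``.
    ``missing_rates`` maps variable names (factors and/or the outcome) to
    independent per-cell missingness probabilities in [0, 1).
    """

    factors: tuple[str, ...]
    joint: PMFJoint | GaussianCopulaJoint
    beta0: float
    beta: np.ndarray
    missing_rates: dict = field(default_factory=dict)
    outcome: str = "poor_outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "beta", beta)
        if self.joint.k != len(self.factors) or len(beta) != len(self.factors):
            raise ValueError("factors, joint and beta dimensions disagree")
        for name, rate in self.missing_rates.items():
            if name not in self.factors and name != self.outcome:
                raise ValueError(f"missing rate for unknown variable {name!r}")
            if not (0.0 <= rate < 1.0):
                raise ValueError("missing rates must lie in [0, 1)")

    @property
    def k(self) -> int:
        return len(self.factors)


@dataclass(frozen=True)
class TruthHandle:
    """How to evaluate ground-truth attributable fractions for a spec."""

    method: str = "exact_enumeration"  # or "monte_carlo"
    mc_n: int = 200_000
    mc_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("exact_enumeration", "monte_carlo"):
            raise ValueError("method must be exact_enumeration or monte_carlo")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    # counter-based splitting: each logical stream gets its own child so
    # adding a stream never perturbs draws in earlier ones
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _draw_profiles(joint, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(joint, PMFJoint):
        idx = rng.choice(len(joint.pmf), size=n, p=joint.pmf)
        return ((idx[:, None] >> np.arange(joint.k)) & 1).astype(float)
    L = np.linalg.cholesky(joint.corr)
    Z = rng.standard_normal((n, joint.k)) @ L.T
    thresh = norm.ppf(1.0 - joint.prevalences)
    return (Z > thresh).astype(float)


def generate(spec: SyntheticSpec, n: int, seed: int | None = None) -> CohortTable:
    """Draw a cohort of ``n`` patients from a synthetic spec.

    Fully reproducible: the same spec and seed give an identical table.
    ``seed=None`` uses ``spec.seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    seed = spec.seed if seed is None else seed
    A = _draw_profiles(spec.joint, n, _rng(seed, _STREAM_EXPOSURE))
    p_out = expit(spec.beta0 + A @ spec.beta)
    y = (_rng(seed, _STREAM_OUTCOME).random(n) < p_out).astype(float)
    data = {spec.outcome: y}
    for j, f in enumerate(spec.factors):
        data[f] = A[:, j].copy()
    frame = pd.DataFrame(data)
    order = [spec.outcome, *spec.factors]
    for stream_offset, name in enumerate(order):
        rate = spec.missing_rates.get(name, 0.0)
        if rate > 0.0:
            rng = _rng(seed, _STREAM_MISSING_BASE + stream_offset)
            frame.loc[rng.random(n) < rate, name] = np.nan
    specs = [VariableSpec(spec.outcome, "binary", "outcome")]
    specs += [VariableSpec(f, "binary", "exposure") for f in spec.factors]
    return CohortTable(frame[order], tuple(specs))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _risk_surfaces(spec: SyntheticSpec, profiles: np.ndarray, S) -> tuple[np.ndarray, np.ndarray]:
    zeroed = profiles.copy()
    for f in S:
        zeroed[:, spec.factors.index(f)] = 0.0
    risk = expit(spec.beta0 + profiles @ spec.beta)
    risk0 = expit(spec.beta0 + zeroed @ spec.beta)
    return risk, risk0


def true_af(spec: SyntheticSpec, S, truth: TruthHandle = TruthHandle()) -> float:
    """True attributable fraction ``1 - E[Y(S -> 0)] / E[Y]`` of a factor set.

    Expectations are over the joint exposure distribution: an exact sum
    over all 2^k profiles for the pmf variant, or a Monte Carlo average of
    the two risk surfaces over ``mc_n`` profile draws.
    """
    S = list(S)
    unknown = [f for f in S if f not in spec.factors]
    if unknown:
        raise KeyError(f"unknown factors {unknown}")
    if truth.method == "exact_enumeration":
        if not isinstance(spec.joint, PMFJoint):
            raise ValueError("exact enumeration requires the pmf joint variant")
        profiles = spec.joint.profiles()
        risk, risk0 = _risk_surfaces(spec, profiles, S)
        ey = float(spec.joint.pmf @ risk)
        ey0 = float(spec.joint.pmf @ risk0)
    else:
        profiles = _draw_profiles(
            spec.joint, truth.mc_n, np.random.default_rng(truth.mc_seed)
        )
        risk, risk0 = _risk_surfaces(spec, profiles, S)
        ey, ey0 = float(risk.mean()), float(risk0.mean())
    return 1.0 - ey0 / ey


def tilted_pmf(base_probs, assoc: float = 0.0) -> PMFJoint:
    """Joint pmf of correlated binaries via pairwise exponential tilting.

    Starts from independent Bernoulli(``base_probs``) and multiplies each
    profile's mass by ``exp(assoc * c)``, where ``c`` is the number of
    concordant exposed pairs in the profile, then renormalizes.
    ``assoc > 0`` induces positive dependence (multimorbidity clustering);
    the base probabilities are weights, not the final marginals.
    """
    p = np.asarray(base_probs, dtype=float)
    k = len(p)
    idx = np.arange(2 ** k)
    profiles = ((idx[:, None] >> np.arange(k)) & 1).astype(float)
    logw = profiles @ np.log(p) + (1.0 - profiles) @ np.log1p(-p)
    pairs = (profiles.sum(axis=1) * (profiles.sum(axis=1) - 1)) / 2.0
    logw = logw + assoc * pairs
    w = np.exp(logw - logw.max())
    return PMFJoint(w / w.sum())


def shapley_weight(subset_size: int, k: int) -> float:
    """Weight ``|S|! (k-|S|-1)! / k!`` of a subset in the Shapley average."""
    return (
        math.factorial(subset_size) * math.factorial(k - subset_size - 1)
        / math.factorial(k)
    )


def true_average_par(
    spec: SyntheticSpec, truth: TruthHandle = TruthHandle()
) -> dict[str, float]:
    """True average (Shapley) PAR per factor.

    Each factor's value is the Shapley-weighted average of its marginal
    contribution ``AF(S ∪ {f}) − AF(S)`` over subsets ``S`` of the other
    factors — equivalently the mean of its sequential contributions over
    all k! removal orderings.  Values sum to ``true_af`` of the full set.
    """
    k = spec.k
    af_cache = {frozenset(): 0.0}

    def af(S: frozenset) -> float:
        if S not in af_cache:
            af_cache[S] = true_af(spec, sorted(S), truth)
        return af_cache[S]

    out = {}
    for f in spec.factors:
        others = [g for g in spec.factors if g != f]
        total = 0.0
        for mask in range(2 ** (k - 1)):
            S = frozenset(others[j] for j in range(k - 1) if (mask >> j) & 1)
            total += shapley_weight(len(S), k) * (af(S | {f}) - af(S))
        out[f] = total
    return out


def true_sequential_af(
    spec: SyntheticSpec, ordering, truth: TruthHandle = TruthHandle()
) -> list[float]:
    """True sequential contributions along one removal ordering."""
    ordering = list(ordering)
    vals = []
    prev = 0.0
    for j in range(1, len(ordering) + 1):
        cur = true_af(spec, ordering[:j], truth)
        vals.append(cur - prev)
        prev = cur
    return vals


# ---------------------------------------------------------------------------
# Preset emulating the study cohort's structure
# ---------------------------------------------------------------------------

#: intercept solved once (2e6 latent draws) so that the preset's expected
#: outcome incidence is 0.205
_PRESET_BETA0 = -2.5372

def proscis_preset(seed: int = 0) -> SyntheticSpec:
    """Five correlated binary risk factors resembling a first-stroke cohort.

    Factors (marginal prevalence, odds ratio): age >= 75 years (0.284,
    2.6), pre-existing physical disability (0.183, 3.0), moderate-or-worse
    stroke severity NIHSS > 4 (0.237, 2.0), education <= 10 years (0.30,
    1.8), diabetes mellitus (0.215, 1.8); exchangeable latent correlation
    0.3 so that most poor-outcome patients are multiply exposed; expected
    poor-outcome incidence 0.205; 1% independent missingness per factor.
    """
    names = ("age75", "disability", "nihss4", "edu10", "diabetes")
    prev = np.array([0.284, 0.183, 0.237, 0.30, 0.215])
    odds = np.array([2.6, 3.0, 2.0, 1.8, 1.8])
    R = np.full((5, 5), 0.3)
    np.fill_diagonal(R, 1.0)
    return SyntheticSpec(
        factors=names,
        joint=GaussianCopulaJoint(prev, R),
        beta0=_PRESET_BETA0,
        beta=np.log(odds),
        missing_rates={f: 0.01 for f in names},
        seed=seed,
    )
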