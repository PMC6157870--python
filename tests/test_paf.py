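"""Attributable-fraction estimators: identities, oracles, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pafkit import (
    CohortTable,
    VariableSpec,
    average_par,
    bootstrap_par,
    combined_af,
    compare_methods,
    coughlin_par,
    doubly_robust_par,
    fit_model,
    generate,
    sequential_af,
    true_af,
)
from pafkit.firth import INTERCEPT, FirthFit


def manual_fit(X, y, beta, names, terms):
    """A FirthFit carrying fixed, externally supplied coefficients."""
    q = len(beta)
    return FirthFit(
        beta=np.asarray(beta, dtype=float), names=names, cov=np.eye(q),
        loglik_pen=0.0, hat=np.zeros(len(y)), iterations=0, converged=True,
        score_norm=0.0, terms=terms, n=len(y), X=X, y=np.asarray(y, dtype=float),
        variables=tuple(terms),
    )


def saturated_2x2_fit(case_exp, ctrl_exp, case_unexp, ctrl_unexp):
    """Unpenalized saturated single-factor model on 2x2 counts."""
    y = np.array([1.0] * (case_exp + case_unexp) + [0.0] * (ctrl_exp + ctrl_unexp))
    x = np.array([1.0] * case_exp + [0.0] * case_unexp
                 + [1.0] * ctrl_exp + [0.0] * ctrl_unexp)
    X = np.column_stack([np.ones_like(y), x])
    beta0 = np.log(case_unexp / ctrl_unexp)
    or_ = (case_exp * ctrl_unexp) / (ctrl_exp * case_unexp)
    return manual_fit(X, y, [beta0, np.log(or_)], (INTERCEPT, "x"), {"x": (1,)})


def random_factor_fit(k, n=400, seed=0, positive=True):
    rng = np.random.default_rng(seed)
    names = tuple(f"f{j}" for j in range(k))
    A = (rng.random((n, k)) < rng.uniform(0.15, 0.45, size=k)).astype(float)
    beta = rng.uniform(0.2, 1.2, size=k)
    if not positive:
        beta = beta * rng.choice([-1.0, 1.0], size=k)
    eta = -1.0 + A @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    X = np.column_stack([np.ones(n), A])
    terms = {f: (j + 1,) for j, f in enumerate(names)}
    return manual_fit(X, y, np.r_[-1.0, beta], (INTERCEPT, *names), terms)


class TestCombinedAF:
    def test_empty_set_is_exactly_zero(self):
        fit = random_factor_fit(3)
        for method in ("bruzzi", "gcomp"):
            assert combined_af(fit, None, [], method=method).value == 0.0

    def test_bruzzi_hand_formula_on_saturated_counts(self):
        # cases 30 exposed / 20 unexposed, controls 70 / 180
        fit = saturated_2x2_fit(30, 70, 20, 180)
        est = combined_af(fit, None, ["x"], method="bruzzi")
        or_ = (30 * 180) / (70 * 20)
        expected = 1.0 - (20 + 30 / or_) / 50.0
        assert est.value == pytest.approx(expected, abs=1e-12)
        assert est.value == pytest.approx(0.4444, abs=5e-5)

    def test_unknown_factor_rejected(self):
        fit = random_factor_fit(2)
        with pytest.raises(KeyError):
            combined_af(fit, None, ["nope"])

    def test_value_never_exceeds_one(self):
        fit = random_factor_fit(4, seed=5)
        for mask in range(16):
            S = [f"f{j}" for j in range(4) if (mask >> j) & 1]
            for method in ("bruzzi", "gcomp"):
                assert combined_af(fit, None, S, method=method).value <= 1.0

    def test_monotone_in_factor_set_under_positive_coefficients(self):
        fit = random_factor_fit(4, seed=2, positive=True)
        subsets = [frozenset(f"f{j}" for j in range(4) if (m >> j) & 1)
                   for m in range(16)]
        for method in ("bruzzi", "gcomp"):
            vals = {S: combined_af(fit, None, sorted(S), method=method).value
                    for S in subsets}
            for S in subsets:
                for T in subsets:
                    if S <= T:
                        assert vals[S] <= vals[T] + 1e-12

    def test_gcomp_recovers_generative_truth(self, k3_spec):
        tab = generate(k3_spec, 20_000, seed=17)
        fit = fit_model(tab, "poor_outcome", list(k3_spec.factors))
        est = combined_af(fit, None, list(k3_spec.factors), method="gcomp")
        truth = true_af(k3_spec, list(k3_spec.factors))
        assert est.value == pytest.approx(truth, abs=0.03)

    def test_rare_outcome_bruzzi_and_gcomp_agree(self, k3_spec):
        # same ORs, incidence pushed to ~1%: odds-ratio AF ~ risk-ratio AF
        from pafkit.synthetic import SyntheticSpec
        rare = SyntheticSpec(k3_spec.factors, k3_spec.joint,
                             k3_spec.beta0 - 3.3, k3_spec.beta)
        tab = generate(rare, 60_000, seed=23)
        assert tab.data["poor_outcome"].mean() < 0.03
        fit = fit_model(tab, "poor_outcome", list(rare.factors))
        for S in (["f1"], ["f1", "f2"], list(rare.factors)):
            b = combined_af(fit, None, S, method="bruzzi").value
            g = combined_af(fit, None, S, method="gcomp").value
            assert b == pytest.approx(g, abs=0.01)

    def test_refit_variant_runs_and_stays_below_one(self, k3_spec):
        tab = generate(k3_spec, 2000, seed=3)
        fit = fit_model(tab, "poor_outcome", list(k3_spec.factors))
        est = combined_af(fit, None, ["f1"], method="gcomp", refit=True)
        assert est.value <= 1.0


class TestSequential:
    def test_single_factor_trace_equals_combined(self):
        fit = random_factor_fit(1, seed=4)
        trace = sequential_af(fit, None, ["f0"])
        assert trace.contributions[0] == pytest.approx(
            combined_af(fit, None, ["f0"]).value, abs=1e-14
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.permutations(["f0", "f1", "f2"]))
    def test_telescoping_sum_equals_full_af(self, seed, ordering):
        fit = random_factor_fit(3, seed=seed)
        trace = sequential_af(fit, None, ordering)
        full = combined_af(fit, None, ["f0", "f1", "f2"]).value
        assert trace.total == pytest.approx(full, abs=1e-10)

    def test_first_position_dominates_last_for_positive_factors(self):
        fit = random_factor_fit(2, seed=8, positive=True)
        first = sequential_af(fit, None, ["f0", "f1"]).contributions[0]
        last = sequential_af(fit, None, ["f1", "f0"]).contributions[1]
        assert first >= last - 1e-12

    def test_non_permutation_rejected(self):
        fit = random_factor_fit(2)
        with pytest.raises(ValueError):
            sequential_af(fit, None, ["f0", "f0"])


class TestAveragePAR:
    def test_enumerate_and_shapley_agree_to_1e12(self):
        for k, seed in [(3, 1), (4, 2)]:
            fit = random_factor_fit(k, seed=seed, positive=False)
            enum = average_par(fit, None, mode="enumerate")
            shap = average_par(fit, None, mode="shapley")
            for f in enum.values:
                assert enum.values[f] == pytest.approx(shap.values[f], abs=1e-12)

    def test_efficiency_sums_to_combined_af(self):
        fit = random_factor_fit(4, seed=3)
        table = average_par(fit, None, mode="shapley")
        full = combined_af(fit, None, [f"f{j}" for j in range(4)]).value
        assert table.total == pytest.approx(full, abs=1e-10)

    def test_exchangeable_factors_get_equal_shares(self):
        # two factors with identical prevalence pattern and coefficient
        y = np.array([1.0] * 40 + [0.0] * 60)
        a = np.r_[np.tile([1.0, 0.0], 20), np.tile([1.0, 0.0], 30)]
        b = np.r_[np.tile([0.0, 1.0], 20), np.tile([0.0, 1.0], 30)]
        X = np.column_stack([np.ones(100), a, b])
        fit = manual_fit(X, y, [-0.5, 0.7, 0.7], (INTERCEPT, "a", "b"),
                         {"a": (1,), "b": (2,)})
        vals = average_par(fit, None, mode="enumerate").values
        assert vals["a"] == pytest.approx(vals["b"], abs=1e-12)

    def test_mode_caps_raise_with_suggestion(self):
        fit = random_factor_fit(3)
        with pytest.raises(ValueError, match="shapley"):
            average_par(fit, None, factors=[f"f{j}" for j in range(3)] * 4,
                        mode="enumerate")


class TestCoughlin:
    def test_single_factor_equals_combined(self):
        fit = random_factor_fit(1, seed=6)
        assert coughlin_par(fit, None, "f0").value == pytest.approx(
            combined_af(fit, None, ["f0"]).value, abs=1e-14
        )

    def test_factorized_cases_make_increments_multiplicative(self):
        # case profiles with exact empirical independence: counts 16/8/8/4
        # then 1 - mean exp factorizes and AF(S∪f)−AF(S) = (1−AF(S))·AF(f)
        profiles = ([(0, 0)] * 16 + [(1, 0)] * 8 + [(0, 1)] * 8 + [(1, 1)] * 4)
        A = np.array(profiles, dtype=float)
        y = np.ones(len(A))
        ctrl = np.zeros((20, 2))
        X = np.column_stack([np.ones(len(A) + 20), np.vstack([A, ctrl])])
        yy = np.r_[y, np.zeros(20)]
        fit = manual_fit(X, yy, [-1.0, 0.8, 0.5], (INTERCEPT, "a", "b"),
                         {"a": (1,), "b": (2,)})
        af_a = combined_af(fit, None, ["a"]).value
        af_b = combined_af(fit, None, ["b"]).value
        af_ab = combined_af(fit, None, ["a", "b"]).value
        assert af_ab - af_b == pytest.approx((1 - af_b) * af_a, abs=1e-12)

    def test_first_removal_dominates_average_under_positive_dependence(self):
        fit = random_factor_fit(3, seed=9, positive=True)
        avg = average_par(fit, None, mode="shapley").values
        for f in avg:
            assert coughlin_par(fit, None, f).value >= avg[f] - 1e-12


class TestDoublyRobust:
    def test_null_factor_par_near_zero(self, k2_independent_spec):
        from pafkit.synthetic import SyntheticSpec
        spec = SyntheticSpec(
            k2_independent_spec.factors, k2_independent_spec.joint,
            -1.5, [0.0, np.log(1.8)],
        )
        pars = []
        for seed in range(8):
            tab = generate(spec, 20_000, seed=seed)
            pars.append(doubly_robust_par(tab, "a", "poor_outcome", ["b"]).par)
        se = np.std(pars, ddof=1) / np.sqrt(len(pars))
        assert abs(np.mean(pars)) <= 3 * max(se, 1e-3)

    def test_estimate_components_within_bounds(self, k3_spec):
        tab = generate(k3_spec, 4000, seed=11)
        dr = doubly_robust_par(tab, "f1", "poor_outcome", ["f2", "f3"])
        assert 0.0 <= dr.ey0 <= 1.0
        assert dr.par <= 1.0
        assert dr.n_clipped == 0

    def test_positivity_violation_raises(self):
        # nearly everyone exposed: intercept-only propensity ~ 0.996
        specs = (VariableSpec("y", "binary", "outcome"),
                 VariableSpec("x", "binary"))
        y = np.r_[np.ones(80), np.zeros(320)]
        x = np.ones(400)
        x[:2] = 0.0
        t = CohortTable(pd.DataFrame({"y": y, "x": x}), specs)
        with pytest.raises(ValueError, match="positivity"):
            doubly_robust_par(t, "x", "y", [])


class TestCompareMethods:
    def test_single_factor_all_methods_rank_first(self, k2_independent_spec):
        tab = generate(k2_independent_spec, 3000, seed=15)
        fit = fit_model(tab, "poor_outcome", ["a"])
        comp = compare_methods(fit, tab)
        assert (comp.table[["average_rank", "doubly_robust_rank",
                            "coughlin_rank"]] == 1).all().all()

    def test_ranks_are_dense_permutations(self, k3_spec):
        tab = generate(k3_spec, 5000, seed=19)
        fit = fit_model(tab, "poor_outcome", list(k3_spec.factors))
        comp = compare_methods(fit, tab)
        for col in ("average_rank", "doubly_robust_rank", "coughlin_rank"):
            assert sorted(comp.table[col]) == [1, 2, 3]

    def test_coughlin_column_dominates_average_column(self, k3_spec):
        tab = generate(k3_spec, 5000, seed=19)
        fit = fit_model(tab, "poor_outcome", list(k3_spec.factors))
        comp = compare_methods(fit, tab)
        assert (comp.table["coughlin"] >= comp.table["average"] - 1e-12).all()


def test_bootstrap_intervals_cover_point_estimates(k2_independent_spec):
    tab = generate(k2_independent_spec, 1200, seed=30)
    fit = fit_model(tab, "poor_outcome", list(k2_independent_spec.factors))
    comp = compare_methods(fit, tab)
    boot = bootstrap_par(tab, "poor_outcome", list(k2_independent_spec.factors),
                         B=30, seed=1)
    for _, row in boot.iterrows():
        point = comp.table.loc[row["factor"], row["method"]]
        assert row["ci_low"] - 0.1 <= point <= row["ci_high"] + 0.1
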