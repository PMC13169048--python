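"""Statistical procedures: exact CIs, contingency switching, stepwise
selection, logistic fits and separation handling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dialdep.inference import (
    DegenerateTableError,
    SeparationError,
    backward_stepwise,
    contingency_test,
    fit_final_model,
    fit_logistic,
    prevalence,
    _fisher_rxc_pvalue,
)
from oracles import fisher_2x2_exact


class TestPrevalence:
    def test_zero_count_lower_bound(self):
        est = prevalence(0, 10)
        assert est.ci_low == 0.0
        assert est.proportion == 0.0

    def test_full_count_upper_bound(self):
        est = prevalence(10, 10)
        assert est.ci_high == 1.0

    def test_exact_interval_for_24_of_300(self):
        est = prevalence(24, 300)
        assert est.proportion == pytest.approx(0.08)
        assert round(100 * est.ci_low, 1) == 5.2
        assert round(100 * est.ci_high, 1) == 11.7

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prevalence(5, 0)
        with pytest.raises(ValueError):
            prevalence(11, 10)

    def test_coverage_is_conservative(self):
        """Exact intervals cover the truth at least nominally (p=0.08, n=300)."""
        rng = np.random.default_rng(2024)
        draws = rng.binomial(300, 0.08, size=2000)
        covered = 0
        for k in np.unique(draws):
            est = prevalence(int(k), 300)
            if est.ci_low <= 0.08 <= est.ci_high:
                covered += int((draws == k).sum())
        assert covered / 2000 >= 0.95


class TestContingency:
    def test_uniform_small_table_routes_to_fisher(self):
        res = contingency_test([[1, 1], [1, 1]])
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(1.0)
        assert res.min_expected_cell == 1.0

    def test_uniform_large_table_routes_to_chi_squared(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.method == "chi_squared"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_switching_rule_keys_on_expected_counts(self):
        # observed min cell 2 but expected cells all >= 5
        res = contingency_test([[2, 48], [28, 22]])
        assert res.min_expected_cell >= 5
        assert res.method == "chi_squared"

    def test_degenerate_margins_rejected(self):
        with pytest.raises(DegenerateTableError):
            contingency_test([[0, 0], [3, 4]])
        with pytest.raises(DegenerateTableError):
            contingency_test([[1, 2]])

    def test_random_small_tables_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = contingency_test([[a, b], [c, d]])
            if res.method == "fisher_exact":
                assert res.p_value == pytest.approx(
                    fisher_2x2_exact(a, b, c, d), rel=1e-9
                )

    def test_rxc_exact_matches_frozen_reference(self):
        # 3x3 reference p computed independently with R 4.3.3 fisher.test
        assert _fisher_rxc_pvalue(np.array([[3, 2, 1], [1, 5, 2], [4, 0, 2]])) == pytest.approx(
            0.1243706, abs=5e-7
        )
        # r x c enumeration agrees with the 2x2 hypergeometric special case
        assert _fisher_rxc_pvalue(np.array([[2, 8], [7, 2]])) == pytest.approx(
            fisher_2x2_exact(2, 8, 7, 2), rel=1e-9
        )


def simulate_logit(n, betas, rng, intercept=-2.5, p_x=0.3):
    X = pd.DataFrame(
        {f"x{i}": (rng.random(n) < p_x).astype(float) for i in range(len(betas))}
    )
    lp = intercept + X.to_numpy() @ np.asarray(betas)
    y = (rng.random(n) < expit(lp)).astype(float)
    return X, y


class TestLogistic:
    def test_null_model_intercept_closed_form(self):
        rng = np.random.default_rng(0)
        n = 5000
        y = (rng.random(n) < 0.08).astype(float)
        X = pd.DataFrame({"x": (rng.random(n) < 0.5).astype(float)})
        res = fit_logistic(X, y)
        p = y.mean()
        assert res.intercept == pytest.approx(np.log(p / (1 - p)), abs=0.15)
        assert res.df == 1

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(12)
        betas = [np.log(5.0), np.log(0.4), 0.8]
        X, y = simulate_logit(50_000, betas, rng)
        res = fit_final_model(X, y)
        for term, beta in zip(res.terms, betas):
            assert abs(term.odds_ratio / np.exp(beta) - 1) < 0.10
        assert res.df == 3
        assert res.model_chi2 > 0 and 0 < res.pseudo_r2 < 1

    def test_wald_ci_brackets_or(self):
        rng = np.random.default_rng(5)
        X, y = simulate_logit(2000, [np.log(3.0)], rng)
        t = fit_logistic(X, y).terms[0]
        assert t.wald_ci_low < t.odds_ratio < t.wald_ci_high
        assert t.odds_ratio == pytest.approx(np.exp(t.coefficient))

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0]})
        with pytest.raises(ValueError):
            fit_logistic(X, np.zeros(3))

    def test_complete_separation_raises_by_default(self):
        X = pd.DataFrame({"x": [0.0] * 10 + [1.0] * 10})
        y = np.array([0.0] * 10 + [1.0] * 10)
        with pytest.raises(SeparationError):
            fit_logistic(X, y)

    def test_firth_fallback_gives_finite_estimates(self):
        X = pd.DataFrame({"x": [0.0] * 10 + [1.0] * 10})
        y = np.array([0.0] * 10 + [1.0] * 10)
        res = fit_logistic(X, y, separation_policy="firth")
        t = res.terms[0]
        assert np.isfinite(t.coefficient) and np.isfinite(t.p_value)
        assert t.odds_ratio > 1


class TestStepwise:
    def test_strong_predictor_retained_null_removed(self):
        rng = np.random.default_rng(21)
        X, y = simulate_logit(2000, [np.log(5.0), 0.0], rng)
        trace = backward_stepwise(X, y, block_id="demo")
        assert [v for v, _ in trace.removal_sequence] == ["x1"]
        assert set(trace.retained) == {"x0"}
        assert trace.retained["x0"] < 0.1
        for _, p in trace.removal_sequence:
            assert p >= 0.1

    def test_all_null_predictors_can_empty_the_block(self):
        rng = np.random.default_rng(26)
        X, y = simulate_logit(2000, [0.0], rng)
        trace = backward_stepwise(X, y)
        assert trace.retained == {}
        assert trace.final_model is None

    def test_deterministic_removal_sequence(self):
        rng = np.random.default_rng(23)
        X, y = simulate_logit(1500, [0.0, 0.0, np.log(4.0)], rng)
        t1 = backward_stepwise(X, y)
        t2 = backward_stepwise(X, y)
        assert t1.removal_sequence == t2.removal_sequence
        assert t1.retained == t2.retained

    def test_grouped_categorical_leaves_as_whole_variable(self):
        rng = np.random.default_rng(24)
        n = 3000
        lev = rng.choice(["a", "b", "c"], size=n)
        X = pd.DataFrame(
            {
                "edu[b]": (lev == "b").astype(float),
                "edu[c]": (lev == "c").astype(float),
                "noise": (rng.random(n) < 0.3).astype(float),
            }
        )
        lp = -2.0 + 1.2 * X["edu[c]"]  # only one level carries signal
        y = (rng.random(n) < expit(lp)).astype(float)
        groups = {"edu": ["edu[b]", "edu[c]"], "noise": ["noise"]}
        trace = backward_stepwise(X, y, groups=groups)
        # the whole education variable survives on its best level's p
        assert "edu" in trace.retained
        assert "noise" not in trace.retained

    def test_lr_stepping_agrees_on_clear_signal(self):
        rng = np.random.default_rng(25)
        X, y = simulate_logit(2000, [np.log(5.0), 0.0], rng)
        trace = backward_stepwise(X, y, p_value_method="lr")
        assert set(trace.retained) == {"x0"}
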