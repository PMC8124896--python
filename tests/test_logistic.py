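"""Logistic IRLS engine, screening workflow and ROC analysis."""

import warnings

import numpy as np
import pytest

from pnetrecur.logistic import (
    ConvergenceError,
    SeparationError,
    build_outcome,
    design_matrix,
    fit_logistic,
    multivariable_model,
    roc_auc,
    univariable_screen,
)
from .oracles import auc_brute_force


def _two_by_two(a, b, c, d):
    """x=1 rows: a cases, b controls; x=0 rows: c cases, d controls."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return x[:, None], y


class TestFitLogistic:
    def test_two_by_two_or_is_cross_product_ratio(self):
        X, y = _two_by_two(10, 20, 5, 40)
        fit = fit_logistic(X, y, names=["exposed"])
        assert fit.table.loc["exposed", "odds_ratio"] == pytest.approx(4.0, abs=1e-9)
        assert fit.converged

    def test_wald_interval_symmetric_in_log_or(self):
        X, y = _two_by_two(10, 20, 5, 40)
        row = fit_logistic(X, y, names=["x"]).table.loc["x"]
        assert row["ci_low"] == pytest.approx(
            np.exp(row["coef"] - 1.96 * row["se"]), abs=1e-12
        )
        assert row["ci_high"] == pytest.approx(
            np.exp(row["coef"] + 1.96 * row["se"]), abs=1e-12
        )

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.arange(10)[:, None], np.zeros(10))

    def test_perfect_separation_raises(self):
        x = np.arange(20, dtype=float)[:, None]
        y = (x[:, 0] >= 10).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(x, y)

    def test_collinear_column_dropped_with_warning(self, rng):
        x1 = rng.normal(size=80)
        X = np.column_stack([x1, 2 * x1])
        y = (x1 + rng.normal(size=80) > 0).astype(float)
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_logistic(X, y, names=["a", "b"])
        assert fit.dropped == ("b",)
        assert list(fit.table.index) == ["a"]

    def test_gradient_norm_below_tolerance_at_solution(self, rng):
        from scipy.special import expit

        for _ in range(10):
            n = 120
            X = rng.normal(size=(n, 3))
            y = (rng.random(n) < expit(X @ [0.5, -0.3, 0.2])).astype(float)
            fit = fit_logistic(X, y, tol=1e-8)
            beta = np.concatenate([[fit.intercept], fit.table["coef"]])
            Xd = np.column_stack([np.ones(n), X])
            grad = Xd.T @ (y - expit(Xd @ beta))
            assert np.max(np.abs(grad)) <= 1e-8

    def test_cross_check_against_statsmodels(self, rng):
        """Coefficients agree with an established GLM fitter to 1e-6 on 100
        random datasets."""
        import statsmodels.api as sm
        from scipy.special import expit

        checked = 0
        while checked < 100:
            n = int(rng.integers(40, 120))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = (rng.random(n) < expit(X @ rng.normal(0.5, 0.3, p))).astype(float)
            if y.sum() in (0, n):
                continue
            try:
                mine = fit_logistic(X, y)
            except (SeparationError, ConvergenceError):
                continue
            theirs = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
            ref = np.asarray(theirs.params)
            beta = np.concatenate([[mine.intercept], mine.table["coef"]])
            assert np.allclose(beta, ref, atol=1e-6)
            checked += 1


class TestScreenAndMultivariable:
    def test_inclusion_flag_is_strict_threshold(self, cohort):
        records, _ = cohort
        screen = univariable_screen(records, outcome_tag="recurrence")
        assert (screen.table["included"] == (screen.table["p"] < 0.10)).all()

    def test_size_and_nodes_screened_in_for_early_model(self, cohort):
        records, _ = cohort
        screen = univariable_screen(records, outcome_tag="early", cutoff_months=18)
        assert "tumor_size" in screen.included
        assert "nodes_positive" in screen.included

    def test_empty_factor_list_rejected(self, cohort):
        records, _ = cohort
        with pytest.raises(ValueError, match="univariable"):
            multivariable_model(records, [], outcome_tag="early")

    def test_multivariable_fit_runs_on_screened_factors(self, cohort):
        records, _ = cohort
        screen = univariable_screen(records, outcome_tag="early")
        fit = multivariable_model(records, screen.included, outcome_tag="early")
        assert fit.converged
        assert set(fit.table.index) <= set(screen.included)

    def test_outcome_tags(self, cohort):
        records, _ = cohort
        y_rec = build_outcome(records, "recurrence")
        y_early = build_outcome(records, "early", 18.0)
        y_late = build_outcome(records, "late", 18.0)
        assert y_rec.sum() == y_early.sum() + y_late.sum()

    def test_design_matrix_missing_as_nan(self):
        from .conftest import make_record

        X = design_matrix([make_record(tumor_size=None, sex=None)],
                          ["tumor_size", "male"])
        assert np.isnan(X.iloc[0]).all()


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == 1.0

    def test_binary_score_closed_form(self, rng):
        y = rng.random(200) < 0.3
        s = (rng.random(200) < 0.6 * y + 0.2).astype(float)
        sens = np.mean(s[y] == 1)
        spec = np.mean(s[~y] == 0)
        assert roc_auc(s, y).auc == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_midrank_ties_match_brute_force(self, rng):
        s = rng.integers(0, 5, 60).astype(float)  # heavy ties
        y = rng.random(60) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert roc_auc(s, y).auc == pytest.approx(auc_brute_force(s, y), abs=1e-12)

    def test_complement_symmetry(self, rng):
        s = rng.normal(size=100)  # ties have probability zero
        y = rng.random(100) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0, abs=1e-12)

    def test_null_scores_near_half(self, rng):
        s = rng.normal(size=10_000)
        y = rng.random(10_000) < 0.5
        assert abs(roc_auc(s, y).auc - 0.5) < 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [True, True])
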