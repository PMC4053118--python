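import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from invasig import (cox_fit, cox_fit_univariate_batch, km_estimate,
                     simulate_survival_cohort, weighted_logrank)
from invasig.survival import _cox_loglik_grad_hess, _event_groups, _prepare
from invasig.synthetic import CohortSimTruth


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_censored_subject_leaves_risk_set_only(self):
        # hand product-limit: (1 - 1/3) at t=1, then (1 - 1/1) at t=3
        km = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km.event_times, [1, 3])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_one_minus_ecdf_without_censoring(self, seed):
        rng = np.random.default_rng(seed)
        t = np.round(rng.exponential(10, 30), 1) + 0.1  # ties included
        km = km_estimate(t, np.ones_like(t, dtype=int))
        for u, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(np.mean(t > u))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        c = simulate_survival_cohort(80, 3, CohortSimTruth(), seed=1)
        km = km_estimate(c.time, c.event)
        kmf = KaplanMeierFitter().fit(c.time, c.event)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(km.survival, theirs, rtol=1e-10)


class TestWeightedLogrank:
    def test_identical_groups_zero_statistic(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a"] * 3 + ["b"] * 3
        res = weighted_logrank(g, t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_accumulated_two_group_fixture(self):
        """A={1,2}, B={3,4}, all events: O-E = 7/6, Var = 17/36, so
        chi2 = (7/6)^2 / (17/36) = 49/17."""
        res = weighted_logrank(["A", "A", "B", "B"], [1, 2, 3, 4], [1] * 4)
        assert res.chi2 == pytest.approx(49 / 17, rel=1e-12)
        assert res.df == 1

    def test_gbw_more_sensitive_to_early_separation(self):
        # groups separate early then converge: heavy early event excess in A
        t = [1, 1, 2, 2, 10, 11, 12, 13, 3, 4, 5, 6, 10, 11, 12, 13]
        e = [1] * 16
        g = ["A"] * 8 + ["B"] * 8
        gbw = weighted_logrank(g, t, e, "gehan-breslow-wilcoxon")
        lr = weighted_logrank(g, t, e, "logrank")
        assert gbw.p < lr.p

    def test_statistic_invariant_under_label_permutation(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 40) + 0.1
        e = (rng.random(40) < 0.7).astype(int)
        g = rng.choice(["x", "y", "z"], 40)
        a = weighted_logrank(g, t, e)
        relabel = {"x": "y", "y": "z", "z": "x"}
        b = weighted_logrank([relabel[v] for v in g], t, e)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
        assert a.df == 2

    def test_matches_lifelines_two_groups(self):
        from lifelines.statistics import logrank_test
        c = simulate_survival_cohort(100, 2, CohortSimTruth(), seed=5)
        g = c.expression.iloc[0].to_numpy() > 0
        ours = weighted_logrank(g.astype(int), c.time, c.event)
        theirs = logrank_test(c.time[g], c.time[~g], c.event[g], c.event[~g])
        assert ours.chi2 == pytest.approx(theirs.test_statistic, rel=1e-9)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            weighted_logrank(["a", "a"], [1, 2], [1, 1])

    def test_unknown_weight_scheme_errors(self):
        with pytest.raises(ValueError):
            weighted_logrank(["a", "b"], [1, 2], [1, 1], "peto")


class TestCoxFit:
    def test_grid_search_oracle_four_subjects(self):
        """The Newton-Raphson MLE equals the partial-likelihood maximizer
        found by brute-force grid search on the 4-subject fixture."""
        def logpl(b):
            return (np.log(np.exp(b) / (2 * np.exp(b) + 2))
                    + np.log(1 / (np.exp(b) + 2))
                    + np.log(np.exp(b) / (np.exp(b) + 1)))
        grid = np.arange(-5, 5, 1e-4)
        best = grid[np.argmax(logpl(grid))]
        fit = cox_fit(np.array([1.0, 0.0, 1.0, 0.0]), [1, 2, 3, 4], [1] * 4)
        assert fit.coefficients[0] == pytest.approx(best, abs=1e-3)
        assert fit.converged
        assert fit.log_partial_likelihood == pytest.approx(
            logpl(fit.coefficients[0]), rel=1e-9)

    def test_score_test_equals_logrank_chi2(self):
        """For a binary covariate without ties, the partial-likelihood
        score test at beta=0 equals the log-rank chi-square."""
        rng = np.random.default_rng(7)
        t = rng.exponential(5, 60) + 0.01
        e = (rng.random(60) < 0.8).astype(int)
        x = (rng.random(60) < 0.5).astype(float)
        ts, es, order = _prepare(t, e)
        groups = _event_groups(ts, es)
        _, grad, hess = _cox_loglik_grad_hess(
            np.zeros(1), x[order][:, None], ts, es, groups, "efron")
        score_chi2 = float(grad[0] ** 2 / -hess[0, 0])
        lr = weighted_logrank(x.astype(int), t, e)
        assert score_chi2 == pytest.approx(lr.chi2, rel=1e-9)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(0)
        n = 120
        x = rng.standard_normal((n, 3))
        t = np.ceil(rng.exponential(50 * np.exp(-0.5 * x[:, 0])))
        e = (rng.random(n) < 0.7).astype(int)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        df["T"], df["E"] = t, e
        theirs = CoxPHFitter().fit(df, "T", "E")
        ours = cox_fit(x, t, e)
        np.testing.assert_allclose(ours.coefficients, theirs.params_.to_numpy(),
                                   atol=1e-4)
        np.testing.assert_allclose(ours.standard_errors,
                                   theirs.standard_errors_.to_numpy(), atol=1e-4)

    def test_gradient_vanishes_and_beats_null_likelihood(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.standard_normal((n, 2))
        t = rng.exponential(10 * np.exp(-0.4 * x[:, 0])) + 0.01
        e = np.ones(n, dtype=int)
        fit = cox_fit(x, t, e)
        ts, es, order = _prepare(t, e)
        groups = _event_groups(ts, es)
        ll0, _, _ = _cox_loglik_grad_hess(np.zeros(2), x[order], ts, es,
                                          groups, "efron")
        _, grad, _ = _cox_loglik_grad_hess(fit.coefficients, x[order], ts, es,
                                           groups, "efron")
        assert fit.log_partial_likelihood >= ll0
        assert np.linalg.norm(grad) < 1e-6

    def test_null_coverage(self):
        """Under the global null, beta-hat lies within 2 SE of zero in at
        least 93 of 100 replicates (Wald coverage)."""
        rng = np.random.default_rng(11)
        inside = 0
        for _ in range(100):
            n = 500
            x = rng.standard_normal(n)
            t = rng.exponential(100, n) + 0.01
            e = (rng.random(n) < 0.6).astype(int)
            fit = cox_fit(x, t, e)
            inside += abs(fit.coefficients[0]) < 2 * fit.standard_errors[0]
        assert inside >= 93

    def test_separation_capped_and_flagged(self):
        # perfect separation: covariate orders the event times exactly
        x = np.array([3.0, 2.0, 1.0, 0.0])
        fit = cox_fit(x, [1, 2, 3, 4], [1, 1, 1, 1])
        assert not fit.converged
        assert abs(fit.coefficients[0]) == 10.0

    def test_constant_covariate_errors_univariate_warns_multivariate(self):
        t, e = [1, 2, 3, 4], [1, 1, 1, 1]
        with pytest.raises(ValueError):
            cox_fit(np.ones(4), t, e)
        X = np.column_stack([np.ones(4), [1.0, 0, 1, 0]])
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(X, t, e, covariate_names=["const", "x"])
        assert fit.covariate_names == ["x"]

    def test_ci_brackets_hazard_ratio(self):
        c = simulate_survival_cohort(
            200, 2, CohortSimTruth(risk_genes=["G00000"],
                                   per_gene_log_hr=[0.5]), seed=2)
        fit = cox_fit(c.expression.loc["G00000"].to_numpy(), c.time, c.event)
        lo, hi = fit.ci95[0]
        assert lo < fit.hazard_ratios[0] < hi

    def test_breslow_vs_efron_differ_only_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        t = rng.exponential(10, 50) + 0.01   # continuous: no ties
        e = np.ones(50, dtype=int)
        a = cox_fit(x, t, e, ties_method="efron")
        b = cox_fit(x, t, e, ties_method="breslow")
        assert a.coefficients[0] == pytest.approx(b.coefficients[0], abs=1e-9)


class TestBatchUnivariate:
    def test_agrees_with_scalar_fit_per_gene(self):
        c = simulate_survival_cohort(90, 12, CohortSimTruth(), seed=6)
        X = c.expression.to_numpy().T
        beta, conv = cox_fit_univariate_batch(X, c.time, c.event)
        assert conv.all()
        for g in range(12):
            single = cox_fit(X[:, g], c.time, c.event)
            assert beta[g] == pytest.approx(single.coefficients[0], abs=2e-4)

    def test_planted_effect_recovered(self):
        truth = CohortSimTruth(risk_genes=["G00000"], per_gene_log_hr=[0.7])
        rng = np.random.default_rng(8)
        betas = []
        for _ in range(50):
            c = simulate_survival_cohort(500, 3, truth,
                                         seed=int(rng.integers(2**31)))
            X = c.expression.to_numpy().T
            b, _ = cox_fit_univariate_batch(X, c.time, c.event)
            betas.append(b[0])
        assert np.mean(betas) == pytest.approx(0.7, abs=0.1)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            cox_fit_univariate_batch(np.ones((3, 1)), [1, 2, 3], [0, 0, 0])
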