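import numpy as np
import pandas as pd
import pytest

from invasig import (GeneSignature, SurvivalCohort, cox_fit,
                     evaluate_stratification, loocv_assign,
                     multivariate_adjustment, risk_index,
                     simulate_survival_cohort, single_fit_assign)
from invasig.risk import assignments_frame
from invasig.synthetic import CohortSimTruth


class TestRiskIndex:
    def test_single_gene_identity(self):
        assert risk_index([2.5], [1.0]) == 2.5

    def test_two_gene_arithmetic(self):
        assert risk_index([2.0, 1.0], [0.5, -1.0]) == 0.0

    def test_brute_force_summation(self):
        rng = np.random.default_rng(0)
        x, b = rng.standard_normal(50), rng.standard_normal(50)
        brute = sum(bi * xi for bi, xi in zip(b, x))
        assert risk_index(x, b) == pytest.approx(brute, abs=1e-12)

    def test_misaligned_errors(self):
        with pytest.raises(ValueError):
            risk_index([1.0, 2.0], [1.0])


def _small_cohort(seed=3, n=40, p=10):
    c = simulate_survival_cohort(n, p + 5, CohortSimTruth(), seed=seed)
    sig = GeneSignature.from_gene_ids([f"G{i:05d}" for i in range(p)])
    return c, sig


class TestLoocvAssign:
    def test_covers_cohort_once(self):
        c, sig = _small_cohort()
        a = loocv_assign(c, sig)
        assert len(a) == c.n_patients
        assert len({x.patient_id for x in a}) == c.n_patients

    def test_group_follows_strict_cutoff_rule(self):
        c, sig = _small_cohort()
        for a in loocv_assign(c, sig):
            assert a.group == ("high" if a.risk_index > a.training_cutoff
                               else "low")

    def test_held_out_patient_does_not_influence_own_fold(self):
        """LOOCV contract: perturbing the held-out patient's expression
        leaves that fold's training (coefficients, cutoff) unchanged --
        only the patient's own risk index may move."""
        c, sig = _small_cohort(seed=9)
        before = loocv_assign(c, sig)
        j = 5
        pid = str(c.patient_ids[j])
        expr = c.expression.copy()
        expr.iloc[:, j] = expr.iloc[:, j] + 50.0
        perturbed = SurvivalCohort(expression=expr, clinical=c.clinical)
        after = loocv_assign(perturbed, sig)
        assert after[j].training_cutoff == pytest.approx(
            before[j].training_cutoff, rel=1e-12)
        assert after[j].risk_index != pytest.approx(before[j].risk_index)

    def test_matches_naive_loop_reimplementation(self):
        """Assignments equal a brute-force re-implementation that loops
        folds and genes naively on a 5-patient, 2-gene cohort."""
        c, _ = _small_cohort(seed=12, n=5, p=2)
        sig = GeneSignature.from_gene_ids(["G00000", "G00001"])
        mine = loocv_assign(c, sig)
        X = c.expression.loc[sig.gene_ids].to_numpy().T
        t, e = c.time, c.event
        for j in range(5):
            mask = np.ones(5, dtype=bool)
            mask[j] = False
            betas = []
            for g in range(2):
                try:
                    fit = cox_fit(X[mask, g], t[mask], e[mask])
                    betas.append(fit.coefficients[0] if fit.converged else 0.0)
                except ValueError:
                    betas.append(0.0)
            betas = np.array(betas)
            cutoff = np.quantile(X[mask] @ betas, 0.8)
            ri = float(X[j] @ betas)
            assert mine[j].risk_index == pytest.approx(ri, abs=1e-9)
            assert mine[j].training_cutoff == pytest.approx(cutoff, abs=1e-9)
            assert mine[j].group == ("high" if ri > cutoff else "low")

    def test_deterministic(self):
        c, sig = _small_cohort()
        a1 = assignments_frame(loocv_assign(c, sig))
        a2 = assignments_frame(loocv_assign(c, sig))
        assert a1.equals(a2)

    def test_scale_equivariance(self):
        """Scaling expression by c > 0 rescales coefficients by 1/c and
        leaves ranks, cutoffs-by-percentile, and groups unchanged."""
        c, sig = _small_cohort(seed=21)
        base = loocv_assign(c, sig)
        scaled_cohort = SurvivalCohort(expression=c.expression * 3.0,
                                       clinical=c.clinical)
        scaled = loocv_assign(scaled_cohort, sig)
        assert [a.group for a in base] == [a.group for a in scaled]
        r_base = np.argsort([a.risk_index for a in base])
        r_scaled = np.argsort([a.risk_index for a in scaled])
        np.testing.assert_array_equal(r_base, r_scaled)

    def test_bad_percentile_rejected(self):
        c, sig = _small_cohort()
        with pytest.raises(ValueError):
            loocv_assign(c, sig, percentile=1.2)

    def test_unmatched_signature_rejected(self):
        c, _ = _small_cohort()
        sig = GeneSignature.from_gene_ids(["NOT_THERE"])
        with pytest.raises(ValueError, match="absent"):
            loocv_assign(c, sig)


class TestEvaluateStratification:
    def test_planted_signature_separates_risk_groups(self, planted_cohort):
        cohort, sig = planted_cohort
        report = evaluate_stratification(loocv_assign(cohort, sig), cohort,
                                         compute_gbw=True)
        assert report.hazard_ratio > 1.5
        assert report.logrank.p < 0.01
        assert report.n_high + report.n_low == cohort.n_patients
        assert report.logrank_gbw is not None

    def test_planted_power_over_replicates(self):
        """The 20-gene planted score yields HR significantly above 1 in
        at least 80% of replicates."""
        risk = [f"G{i:05d}" for i in range(20)]
        truth = CohortSimTruth(risk_genes=risk,
                               per_gene_log_hr=[1 / np.sqrt(20)] * 20)
        sig = GeneSignature.from_gene_ids(risk)
        rng = np.random.default_rng(13)
        wins = 0
        n_rep = 12
        for _ in range(n_rep):
            c = simulate_survival_cohort(200, 40, truth,
                                         seed=int(rng.integers(2**31)))
            rep = evaluate_stratification(loocv_assign(c, sig), c)
            wins += rep.hr_ci95[0] > 1.0
        assert wins / n_rep >= 0.8

    def test_incomplete_assignments_rejected(self):
        c, sig = _small_cohort()
        a = loocv_assign(c, sig)
        with pytest.raises(ValueError, match="cover"):
            evaluate_stratification(a[:-1], c)

    def test_single_fit_is_fast_approximation(self):
        c, sig = _small_cohort(seed=14, n=60)
        a = single_fit_assign(c, sig)
        assert len(a) == 60
        assert all(x.fold_id == -1 for x in a)
        # the full-data fit concentrates high-risk calls in the top tail
        frac_high = np.mean([x.group == "high" for x in a])
        assert frac_high == pytest.approx(0.2, abs=0.05)


class TestMultivariateAdjustment:
    def test_unconfounded_covariates_leave_hr_unchanged(self):
        risk = [f"G{i:05d}" for i in range(5)]
        truth = CohortSimTruth(risk_genes=risk,
                               per_gene_log_hr=[0.3] * 5,
                               covariate_mixing=0.0)
        c = simulate_survival_cohort(250, 20, truth, seed=15)
        sig = GeneSignature.from_gene_ids(risk)
        a = loocv_assign(c, sig)
        unadj = evaluate_stratification(a, c).hazard_ratio
        adj = multivariate_adjustment(c, a, ["grade", "node", "size", "er"])
        assert adj.summary()["high_risk"]["hr"] == pytest.approx(unadj,
                                                                 rel=0.15)

    def test_confounding_attenuates_group_hr(self):
        """When a clinical covariate drives both the hazard and the
        expression that defines the groups, adjustment attenuates the
        group hazard ratio."""
        rng = np.random.default_rng(16)
        n = 300
        z = rng.standard_normal(n)
        expr = pd.DataFrame(
            {f"P{j:04d}": [z[j] + 0.3 * rng.standard_normal()] for j in range(n)},
            index=["G00000"])
        t = rng.exponential(1 / (0.01 * np.exp(0.9 * z))) + 0.01
        clin = pd.DataFrame({
            "time_months": t, "event": np.ones(n, dtype=int),
            "grade": np.where(z + 0.4 * rng.standard_normal(n) > 0, 3, 1),
            "node": (z + 0.6 * rng.standard_normal(n) > 0).astype(int),
            "size_cm": 2.0 + 0.5 * z + 0.2 * rng.standard_normal(n),
            "er": rng.integers(0, 2, n), "subtype": "basal",
        }, index=expr.columns)
        c = SurvivalCohort(expression=expr, clinical=clin)
        sig = GeneSignature.from_gene_ids(["G00000"])
        a = loocv_assign(c, sig)
        unadj = evaluate_stratification(a, c).hazard_ratio
        adj = multivariate_adjustment(c, a, ["grade", "node", "size"])
        assert adj.summary()["high_risk"]["hr"] < unadj

    def test_unknown_covariate_rejected(self):
        c, sig = _small_cohort()
        a = loocv_assign(c, sig)
        with pytest.raises(ValueError, match="unknown covariate"):
            multivariate_adjustment(c, a, ["stage"])

    def test_external_score_covariate(self):
        c, sig = _small_cohort(seed=17, n=60)
        a = loocv_assign(c, sig)
        score = np.arange(60, dtype=float)
        fit = multivariate_adjustment(c, a, ["external_score"],
                                      external_score=score)
        assert "external_score" in fit.covariate_names
        with pytest.raises(ValueError, match="not supplied"):
            multivariate_adjustment(c, a, ["external_score"])


class TestSubsetRobustness:
    def test_subtype_exclusion_equals_subset_run(self):
        """Excluding one subtype and re-running equals running on the
        subset cohort directly: no hidden global state."""
        c, sig = _small_cohort(seed=18, n=80)
        reduced = c.drop_subtype("basal")
        assert reduced.n_patients < c.n_patients
        a1 = assignments_frame(loocv_assign(reduced, sig))
        keep = c.clinical.index[c.clinical["subtype"] != "basal"]
        a2 = assignments_frame(loocv_assign(c.subset_patients(keep), sig))
        assert a1.equals(a2)
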