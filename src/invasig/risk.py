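"""Leave-one-out cross-validated risk-index classification.

For each held-out patient, every signature gene is fit in a univariate
Cox model on the remaining patients; the held-out patient's risk index is
the linear combination of their expression values weighted by those
coefficients (RI_j = sum_g beta_g x_gj).  A patient whose index falls in
the top 20th percentile of the training indices is assigned to the
high-risk group.  The resulting high/low stratification is evaluated by
Kaplan-Meier curves, the log-rank test, and a Cox fit on the group
indicator; a multivariate Cox adjusts for clinical covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSignature, SurvivalCohort
from .survival import (CoxFit, KMCurve, LogRankResult, cox_fit,
                       cox_fit_univariate_batch, km_estimate, weighted_logrank)

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 0.80  # "top 20th percentile" => cutoff at the 80th


@dataclass
class RiskAssignment:
    patient_id: str
    risk_index: float
    group: str                 # "high" | "low"
    training_cutoff: float
    fold_id: int


@dataclass
class StratificationReport:
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogRankResult
    hazard_ratio: float
    hr_ci95: tuple
    hr_p: float
    n_high: int
    n_low: int
    cox: CoxFit
    logrank_gbw: LogRankResult | None = None

    def to_dict(self) -> dict:
        return {
            "n_high": self.n_high, "n_low": self.n_low,
            "logrank_chi2": self.logrank.chi2, "logrank_p": self.logrank.p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci95": list(self.hr_ci95), "hr_p": self.hr_p,
            "gehan_breslow_wilcoxon_p":
                self.logrank_gbw.p if self.logrank_gbw else None,
        }


def risk_index(expression_vector, coefficients) -> float:
    """RI = sum_g beta_g * x_g for aligned gene vectors."""
    x = np.asarray(expression_vector, dtype=float)
    b = np.asarray(coefficients, dtype=float)
    if x.shape != b.shape:
        raise ValueError("expression vector and coefficients are misaligned")
    return float(b @ x)


def _signature_matrix(cohort: SurvivalCohort, signature: GeneSignature) -> np.ndarray:
    genes = signature.gene_ids
    missing = [g for g in genes if g not in cohort.gene_ids]
    if missing:
        raise ValueError(
            f"signature genes absent from cohort (match it first): {missing[:5]}")
    return cohort.expression.loc[genes].to_numpy(dtype=float).T  # patients x genes


def loocv_assign(cohort: SurvivalCohort, signature: GeneSignature,
                 percentile: float = DEFAULT_PERCENTILE,
                 standardize: bool = False) -> list[RiskAssignment]:
    """Leave-one-out cross-validated risk index and high/low assignment.

    Deterministic: no randomness is involved.  In each fold the held-out
    patient's index is compared against the empirical ``percentile``
    quantile (linear interpolation) of the training indices; strictly
    above means high risk.  Univariate fits that fail to converge in a
    fold contribute a zero coefficient there (logged).

    ``standardize`` optionally z-scores each gene within the training
    fold (and applies the training transform to the held-out patient);
    off by default.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    X = _signature_matrix(cohort, signature)     # n x p
    time, event = cohort.time, cohort.event
    n = X.shape[0]

    assignments = []
    n_nonconverged = 0
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        X_tr = X[mask]
        if standardize:
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            x_te = (X[j] - mu) / sd
        else:
            x_te = X[j]
        beta, conv = cox_fit_univariate_batch(X_tr, time[mask], event[mask])
        if not conv.all():
            n_nonconverged += int((~conv).sum())
            beta = np.where(conv, beta, 0.0)
        ri_train = X_tr @ beta
        cutoff = float(np.quantile(ri_train, percentile))
        ri = risk_index(x_te, beta)
        assignments.append(RiskAssignment(
            patient_id=str(cohort.patient_ids[j]),
            risk_index=ri,
            group="high" if ri > cutoff else "low",
            training_cutoff=cutoff,
            fold_id=j,
        ))
    if n_nonconverged:
        logger.info("%d non-convergent univariate fits zeroed across folds",
                    n_nonconverged)
    return assignments


def single_fit_assign(cohort: SurvivalCohort, signature: GeneSignature,
                      percentile: float = DEFAULT_PERCENTILE) -> list[RiskAssignment]:
    """Fast approximation to :func:`loocv_assign`: one batch of univariate
    Cox fits on the full cohort, indices and percentile cutoff computed
    once.  Used where thousands of signatures must be screened; it is an
    approximation, not the cross-validated procedure.
    """
    X = _signature_matrix(cohort, signature)
    beta, conv = cox_fit_univariate_batch(X, cohort.time, cohort.event)
    beta = np.where(conv, beta, 0.0)
    ri = X @ beta
    cutoff = float(np.quantile(ri, percentile))
    return [
        RiskAssignment(patient_id=str(pid), risk_index=float(r),
                       group="high" if r > cutoff else "low",
                       training_cutoff=cutoff, fold_id=-1)
        for pid, r in zip(cohort.patient_ids, ri)
    ]


def assignments_frame(assignments: list[RiskAssignment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": a.patient_id, "risk_index": a.risk_index,
        "group": a.group, "training_cutoff": a.training_cutoff,
        "fold_id": a.fold_id,
    } for a in assignments])


def evaluate_stratification(assignments: list[RiskAssignment],
                            cohort: SurvivalCohort,
                            compute_gbw: bool = False) -> StratificationReport:
    """KM curves, log-rank p, and Cox hazard ratio for high vs low risk."""
    frame = assignments_frame(assignments).set_index("patient_id")
    ids = [str(p) for p in cohort.patient_ids]
    if set(frame.index) != set(ids):
        raise ValueError("assignments do not cover the cohort exactly")
    group = frame.loc[ids, "group"].to_numpy()
    n_high, n_low = int((group == "high").sum()), int((group == "low").sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("degenerate stratification: one group is empty")

    time, event = cohort.time, cohort.event
    hi = group == "high"
    km_high = km_estimate(time[hi], event[hi])
    km_low = km_estimate(time[~hi], event[~hi])
    lr = weighted_logrank(group, time, event, "logrank")
    gbw = weighted_logrank(group, time, event, "gehan-breslow-wilcoxon") \
        if compute_gbw else None
    fit = cox_fit(hi.astype(float), time, event, covariate_names=["high_risk"])
    ci = fit.ci95[0]
    return StratificationReport(
        km_high=km_high, km_low=km_low, logrank=lr,
        hazard_ratio=float(fit.hazard_ratios[0]),
        hr_ci95=(float(ci[0]), float(ci[1])),
        hr_p=float(fit.wald_p[0]),
        n_high=n_high, n_low=n_low, cox=fit, logrank_gbw=gbw,
    )


COVARIATE_CODING = {
    # grade enters ordinal-linear; node, er binary; size continuous (cm)
    "grade": lambda c: c["grade"].to_numpy(dtype=float),
    "node": lambda c: c["node"].to_numpy(dtype=float),
    "size": lambda c: c["size_cm"].to_numpy(dtype=float),
    "er": lambda c: c["er"].to_numpy(dtype=float),
}


def multivariate_adjustment(cohort: SurvivalCohort,
                            assignments: list[RiskAssignment],
                            covariate_spec: list[str],
                            external_score: np.ndarray | None = None) -> CoxFit:
    """Multivariate Cox: high/low indicator plus requested clinical
    covariates (subset of grade, node, size, er, external_score).

    ``external_score`` supplies a per-patient score for a published
    signature entered as a continuous covariate.
    """
    frame = assignments_frame(assignments).set_index("patient_id")
    ids = [str(p) for p in cohort.patient_ids]
    group = (frame.loc[ids, "group"] == "high").to_numpy(dtype=float)

    cols, names = [group], ["high_risk"]
    for cov in covariate_spec:
        if cov == "external_score":
            if external_score is None:
                raise ValueError("external_score requested but not supplied")
            cols.append(np.asarray(external_score, dtype=float))
        elif cov in COVARIATE_CODING:
            cols.append(COVARIATE_CODING[cov](cohort.clinical))
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        names.append(cov)
    X = np.column_stack(cols)
    return cox_fit(X, cohort.time, cohort.event, covariate_names=names)
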