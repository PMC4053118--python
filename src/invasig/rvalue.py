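"""Per-patient signature-correlation R-values, grouped by subtype.

The R-value of a tumor is the Pearson correlation between a signature's
+/-1 up/down pattern and the tumor's (centroid-centered) expression over
the signature genes: high when the up-regulated genes are high and the
down-regulated genes are low.  Expression is first centered per gene on
the centroid mean — the mean of the two comparison-group means — so that
R measures resemblance to the signature pattern rather than to overall
abundance.  Significance of each R uses the usual t-transform with
(n_genes - 2) degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSignature, SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass
class RValueResult:
    patient_id: str
    r: float
    p: float
    subtype: str
    n_genes_used: int


def centroid_center(matrix: ExpressionMatrix, group_labels) -> ExpressionMatrix:
    """Center each gene on the mean of the two group means.

    ``group_labels`` maps sample id -> one of exactly two groups; both
    must be non-empty.
    """
    labels = pd.Series(group_labels)
    levels = sorted(pd.unique(labels.loc[matrix.sample_ids]))
    if len(levels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {levels}")
    values = matrix.values
    in_a = labels.loc[matrix.sample_ids].to_numpy() == levels[0]
    mean_a = values.loc[:, in_a].mean(axis=1)
    mean_b = values.loc[:, ~in_a].mean(axis=1)
    centroid = (mean_a + mean_b) / 2.0
    return ExpressionMatrix(values=values.sub(centroid, axis=0),
                            class_labels=matrix.class_labels)


def r_value(patient_vector, signature: GeneSignature,
            patient_id: str = "", subtype: str = "") -> RValueResult:
    """Pearson correlation of a patient's (centered) signature-gene
    expression with the signature's +/-1 direction pattern.
    """
    x = np.asarray(patient_vector, dtype=float)
    pattern = signature.directions
    if x.shape != pattern.shape:
        raise ValueError("patient vector is not aligned to the signature genes")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 genes for a correlation")
    if np.ptp(x) == 0 or np.ptp(pattern) == 0:
        logger.warning("zero-variance vector for patient %s: r undefined", patient_id)
        return RValueResult(patient_id=patient_id, r=np.nan, p=np.nan,
                            subtype=subtype, n_genes_used=n)
    r, p = stats.pearsonr(pattern, x)
    return RValueResult(patient_id=patient_id, r=float(r), p=float(p),
                        subtype=subtype, n_genes_used=n)


def significance_cutoff(n_genes: int, alpha: float = 0.05) -> float:
    """|r| above which the correlation is two-sided significant at alpha
    for ``n_genes`` observations (t-transform with n - 2 df)."""
    df = n_genes - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(tcrit / np.sqrt(df + tcrit**2))


def rvalue_by_subtype(cohort: SurvivalCohort, signature: GeneSignature,
                      comparison_groups=None) -> list[RValueResult]:
    """R-value per patient after centroid centering, tagged by subtype.

    ``comparison_groups`` maps patient id -> one of two groups used for
    the centroid centering; typical choice is the high/low risk groups
    from the LOOCV classifier.  Patients with missing subtype are grouped
    under "unknown".
    """
    genes = [g for g in signature.gene_ids if g in cohort.gene_ids]
    if len(genes) < len(signature):
        logger.info("r-value uses %d/%d signature genes present in cohort",
                    len(genes), len(signature))
    sig = GeneSignature(signature.table[signature.table["gene_id"].isin(genes)]
                        .reset_index(drop=True))
    sub = ExpressionMatrix(values=cohort.expression.loc[sig.gene_ids])

    if comparison_groups is None:
        raise ValueError("comparison_groups required (e.g. high/low risk groups)")
    centered = centroid_center(sub, comparison_groups)

    subtype = cohort.clinical["subtype"] if "subtype" in cohort.clinical else None
    results = []
    for pid in cohort.patient_ids:
        st = "unknown"
        if subtype is not None:
            val = subtype.loc[pid]
            st = str(val) if pd.notna(val) else "unknown"
        results.append(r_value(centered.values[pid].to_numpy(), sig,
                               patient_id=str(pid), subtype=st))
    return results


def rvalues_frame(results: list[RValueResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": r.patient_id, "r": r.r, "p": r.p,
        "subtype": r.subtype, "n_genes_used": r.n_genes_used,
    } for r in results])
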