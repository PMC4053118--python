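"""Two-channel array preprocessing and cohort-side gene matching.

* :func:`lowess_normalize` — global intensity-dependent (MA) normalization
  per array: a locally weighted linear fit of M = log2(R/G) on
  A = (log2 R + log2 G)/2 is subtracted from M.
* :func:`filter_and_collapse` — probe filtering/imputation and
  probe-to-gene collapsing by greatest across-sample variation.
* :func:`match_signature_to_cohort` — restrict a signature to the genes a
  validation cohort actually measured.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .containers import ExpressionMatrix, GeneSignature, SurvivalCohort

logger = logging.getLogger(__name__)


def lowess_normalize(red_intensity: pd.DataFrame, green_intensity: pd.DataFrame,
                     smoother_span: float = 0.3, iterations: int = 3) -> ExpressionMatrix:
    """Global LOWESS (MA) normalization of two-channel intensities.

    Rows with a non-positive intensity in either channel on any array are
    filtered (logged), since their log-ratios are undefined.  The smoother
    is local linear with ``smoother_span`` fraction of the data and
    ``iterations`` robustness reweightings.
    """
    red = pd.DataFrame(red_intensity)
    green = pd.DataFrame(green_intensity)
    if red.shape != green.shape:
        raise ValueError("channel matrices must have the same shape")
    if not (0 < smoother_span <= 1):
        raise ValueError("smoother_span must be in (0, 1]")

    bad = ((red <= 0) | (green <= 0)).any(axis=1)
    if bad.any():
        logger.info("filtering %d rows with non-positive intensities", int(bad.sum()))
        red, green = red.loc[~bad], green.loc[~bad]

    M = np.log2(red.to_numpy(dtype=float)) - np.log2(green.to_numpy(dtype=float))
    A = 0.5 * (np.log2(red.to_numpy(dtype=float)) + np.log2(green.to_numpy(dtype=float)))
    norm = np.empty_like(M)
    for j in range(M.shape[1]):
        trend = sm_lowess(M[:, j], A[:, j], frac=smoother_span, it=iterations,
                          return_sorted=False)
        norm[:, j] = M[:, j] - trend
    values = pd.DataFrame(norm, index=red.index, columns=red.columns)
    return ExpressionMatrix(values=values, probe_ids=values.index)


def filter_and_collapse(matrix: ExpressionMatrix, probe_to_gene: dict | pd.Series,
                        variation: str = "variance",
                        max_missing_frac: float = 0.2) -> ExpressionMatrix:
    """Collapse probes to genes, keeping the probe with greatest variation.

    Probes without a gene mapping are dropped.  Probes missing in more
    than ``max_missing_frac`` of samples are filtered; remaining missing
    entries are imputed with the probe median.  ``variation`` is
    "variance" (default) or "mad".  Variance ties break to the
    lexicographically smallest probe id.
    """
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("empty probe-to-gene mapping")
    if variation not in ("variance", "mad"):
        raise ValueError(f"unknown variation measure {variation!r}")

    values = matrix.values
    mapped = values.index.intersection(mapping.index)
    dropped = len(values.index) - len(mapped)
    if dropped:
        logger.info("dropping %d probes with no gene mapping", dropped)
    values = values.loc[mapped]

    frac_missing = values.isna().mean(axis=1)
    keep = frac_missing <= max_missing_frac
    if (~keep).any():
        logger.info("filtering %d probes with >%.0f%% missing values",
                    int((~keep).sum()), 100 * max_missing_frac)
    values = values.loc[keep]
    if values.isna().any().any():
        med = values.median(axis=1)
        values = values.T.fillna(med).T

    if variation == "variance":
        spread = values.var(axis=1, ddof=1)
    else:
        spread = (values.sub(values.median(axis=1), axis=0)).abs().median(axis=1)

    genes = mapping.loc[values.index]
    pick = (
        pd.DataFrame({"gene": genes.to_numpy(), "spread": spread.to_numpy(),
                      "probe": values.index})
        .sort_values(["gene", "spread", "probe"],
                     ascending=[True, False, True], kind="stable")
        .drop_duplicates("gene")
    )
    collapsed = values.loc[pick["probe"]]
    collapsed.index = pd.Index(pick["gene"], name="gene_id")
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(values=collapsed, class_labels=matrix.class_labels)


def match_signature_to_cohort(signature: GeneSignature,
                              cohort: SurvivalCohort) -> GeneSignature:
    """Restrict a signature to the genes measured in the cohort.

    The number of dropped genes is logged; a zero-overlap signature is an
    error because it cannot be evaluated at all.
    """
    present = signature.table["gene_id"].isin(cohort.gene_ids)
    n_dropped = int((~present).sum())
    if present.sum() == 0:
        raise ValueError("signature and cohort share no genes")
    if n_dropped:
        logger.info("signature matching dropped %d/%d genes absent from cohort",
                    n_dropped, len(signature))
    return GeneSignature(signature.table[present].reset_index(drop=True))
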