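"""Orchestration: configuration, derivation and validation runs, reports.

``run_derive`` chains preprocessing -> SAM permutation FDR -> significance
calling -> top-k-by-fold signature extraction.  ``run_validate`` chains
signature/cohort matching -> LOOCV risk assignment -> stratification
evaluation -> multivariate adjustment -> random-signature null ->
subtype R-values, and writes a single JSON report plus TSV artifacts.

Artifacts embed the config hash and seed and contain no timestamps, so a
re-run with the same config is byte-identical.  All files are written to
a temporary name and atomically renamed, so partial failures never leave
truncated outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GeneSignature, SurvivalCohort
from .preprocess import filter_and_collapse, match_signature_to_cohort
from .risk import (DEFAULT_PERCENTILE, assignments_frame,
                   evaluate_stratification, loocv_assign,
                   multivariate_adjustment)
from .rvalue import rvalue_by_subtype, rvalues_frame, significance_cutoff
from .sam import call_significant, extract_signature, sam_permutation_fdr
from .signature_null import empirical_specificity, null_distribution

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a derivation/validation run.

    Defaults mirror the analysis this package implements: a 10% FDR
    target for the differential-expression call, the top 80 genes by fold
    change as the prognostic subset, the 80th-percentile risk-index
    cutoff, and 1,000 random signatures for the specificity null.
    """

    expression_path: str | None = None
    labels: dict | None = None          # sample id -> class
    probe_map_path: str | None = None
    clinical_path: str | None = None
    signature_path: str | None = None
    output_dir: str = "invasig_out"

    fdr_target: float = 0.10
    top_k: int = 80
    percentile: float = DEFAULT_PERCENTILE
    n_permutations: int = 300
    M: int = 1000
    null_fast: bool = False
    covariate_spec: list = field(default_factory=list)
    exclude_subtype: str | None = None
    seed: int = 0

    def __post_init__(self):
        for name, val in (("fdr_target", self.fdr_target),
                          ("percentile", self.percentile)):
            if not 0 < val < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        for name, val in (("top_k", self.top_k), ("M", self.M),
                          ("n_permutations", self.n_permutations)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _atomic_write(path: Path, writer) -> None:
    """Write via temp file + rename so readers never see a partial file."""
    tmp = path.with_name(path.name + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    _atomic_write(path, lambda p: df.to_csv(p, sep="\t", index=index))


def _write_json(obj, path: Path) -> None:
    _atomic_write(path, lambda p: Path(p).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n"))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_derive(config: RunConfig,
               matrix: ExpressionMatrix | None = None) -> GeneSignature:
    """Derive a signature: (collapse) -> SAM -> FDR call -> top-k by fold.

    ``matrix`` may be passed directly; otherwise it is read from
    ``config.expression_path`` with ``config.labels``.  Artifacts: SAM
    gene table, delta table, signature TSV, and a JSON run log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        if config.expression_path is None or config.labels is None:
            raise ValueError("need expression_path and labels (or a matrix)")
        matrix = ExpressionMatrix.from_tsv(config.expression_path, config.labels)
    if config.probe_map_path:
        probe_map = pd.read_csv(config.probe_map_path, sep="\t",
                                index_col=0).iloc[:, 0]
        matrix = filter_and_collapse(matrix, probe_map)

    result = sam_permutation_fdr(matrix, n_permutations=config.n_permutations,
                                 seed=config.seed)
    result = call_significant(result, target_fdr=config.fdr_target)
    n_called = int(result.called.sum())
    signature = extract_signature(result, k=config.top_k)
    if n_called == 0:
        logger.warning("FDR target %.2f unreachable: empty signature",
                       config.fdr_target)
        _write_json({"warning": "fdr_target_unreachable",
                     "target_fdr": config.fdr_target,
                     "config_hash": config.config_hash(), "seed": config.seed},
                    out / "derive_warning.json")

    _write_tsv(result.to_frame(), out / "sam_genes.tsv")
    _write_tsv(result.delta_table, out / "sam_delta_table.tsv")
    _atomic_write(out / "signature.tsv", signature.to_tsv)
    _write_json({
        "stage": "derive", "config": config.to_dict(),
        "config_hash": config.config_hash(), "seed": config.seed,
        "s0": result.s0, "chosen_delta": result.chosen_delta,
        "n_called": n_called, "signature_size": len(signature),
        "n_permutations": result.n_permutations,
    }, out / "derive_report.json")
    return signature


def _km_frame(km) -> pd.DataFrame:
    return pd.DataFrame({
        "time_months": km.event_times, "survival": km.survival,
        "n_at_risk": km.n_at_risk, "n_events": km.n_events,
    })


def run_validate(config: RunConfig,
                 cohort: SurvivalCohort | None = None,
                 signature: GeneSignature | None = None) -> dict:
    """Validate a signature on a cohort end to end.

    Stages: match -> LOOCV assign -> stratification (KM, log-rank, HR) ->
    multivariate adjustment (if covariates requested) -> random-signature
    null (M draws) -> R-values by subtype.  Returns the report dict and
    writes report.json plus assignment/KM/null/R-value TSVs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        if config.expression_path is None or config.clinical_path is None:
            raise ValueError("need expression_path and clinical_path (or a cohort)")
        cohort = SurvivalCohort.from_tsv(config.expression_path,
                                         config.clinical_path)
    if signature is None:
        if config.signature_path is None:
            raise ValueError("need signature_path (or a signature)")
        signature = GeneSignature.from_tsv(config.signature_path)
    if config.exclude_subtype:
        cohort = cohort.drop_subtype(config.exclude_subtype)
        logger.info("excluded subtype %s; %d patients remain",
                    config.exclude_subtype, cohort.n_patients)

    matched = match_signature_to_cohort(signature, cohort)
    assignments = loocv_assign(cohort, matched, percentile=config.percentile)
    report = evaluate_stratification(assignments, cohort, compute_gbw=True)

    adjusted = None
    if config.covariate_spec:
        adjusted = multivariate_adjustment(cohort, assignments,
                                           config.covariate_spec)

    null = null_distribution(cohort, size=len(matched), M=config.M,
                             percentile=config.percentile, seed=config.seed,
                             fast=config.null_fast)
    specificity = empirical_specificity(report.logrank.p, null)

    groups = {a.patient_id: a.group for a in assignments}
    rvals = rvalue_by_subtype(cohort, matched, comparison_groups=groups)

    _write_tsv(assignments_frame(assignments), out / "assignments.tsv")
    _write_tsv(_km_frame(report.km_high), out / "km_high.tsv")
    _write_tsv(_km_frame(report.km_low), out / "km_low.tsv")
    _write_tsv(pd.DataFrame({"p_value": null.p_values}), out / "null_pvalues.tsv")
    _write_tsv(rvalues_frame(rvals), out / "rvalues.tsv")

    summary = {
        "stage": "validate", "config": config.to_dict(),
        "config_hash": config.config_hash(), "seed": config.seed,
        "n_patients": cohort.n_patients,
        "signature_size_matched": len(matched),
        "stratification": report.to_dict(),
        "multivariate": adjusted.summary() if adjusted is not None else None,
        "null": {
            "M": null.M, "fast_mode": null.fast_mode,
            "observed_p": specificity.observed_p,
            "empirical_tail": specificity.empirical_tail,
            "best5_cutoff": specificity.best5_cutoff,
            "beats_best5": specificity.beats_best5,
        },
        "rvalue": {
            "significance_cutoff_r": significance_cutoff(len(matched)),
            "median_r_by_subtype": rvalues_frame(rvals)
                .groupby("subtype")["r"].median().to_dict(),
        },
    }
    _write_json(summary, out / "report.json")
    return summary
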