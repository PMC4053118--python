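"""Synthetic data with known planted structure.

Two generators stand in for the study data that the pipeline analyzes:

* :func:`simulate_two_class_expression` emulates a two-channel microarray
  comparison of a migratory tumor-cell population against the average
  primary-tumor population: a genes x samples log2-ratio matrix in which a
  chosen subset of genes carries a planted mean shift between the classes.
* :func:`simulate_survival_cohort` emulates an expression + clinical
  validation cohort (NKI295/UNC232-like): per-gene standard-normal
  expression, exponential proportional-hazards event times driven by a
  known subset of risk genes, independent exponential censoring plus an
  administrative cutoff, and intrinsic-subtype / clinical covariates with
  documented marginals.

Every downstream stage is tested against the ground truth these
generators record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import as_generator
from .containers import ExpressionMatrix, SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass
class TwoClassSimTruth:
    """Ground truth for a planted two-class expression simulation."""

    de_flags: np.ndarray            # per-gene 0/1 indicator of planted DE
    de_log2_effects: np.ndarray     # per-gene planted class-mean log2 shift
    noise_sd: float
    seed: int | None

    def __post_init__(self):
        self.de_flags = np.asarray(self.de_flags, dtype=int)
        self.de_log2_effects = np.asarray(self.de_log2_effects, dtype=float)
        if len(self.de_flags) != len(self.de_log2_effects):
            raise ValueError("de_flags and de_log2_effects lengths differ")
        if np.any((self.de_flags == 0) & (self.de_log2_effects != 0)):
            raise ValueError("effects must be 0 exactly where de_flags is 0")

    @property
    def de_gene_ids(self) -> list:
        return [f"G{i:05d}" for i in np.flatnonzero(self.de_flags)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["de_flags"] = self.de_flags.tolist()
        d["de_log2_effects"] = self.de_log2_effects.tolist()
        return d


@dataclass
class CohortSimTruth:
    """Ground truth and parameters for a proportional-hazards cohort.

    ``per_gene_log_hr`` is the log hazard ratio per unit expression for
    each gene in ``risk_genes``; the linear predictor of patient j is
    sum_g log_hr_g * x_gj and the event time is exponential with rate
    baseline_hazard * exp(linear predictor).  ``censor_rate`` is the rate
    of an independent exponential censoring time; ``admin_cutoff``
    truncates follow-up administratively (months).
    """

    risk_genes: list = field(default_factory=list)
    per_gene_log_hr: list = field(default_factory=list)
    baseline_hazard: float = 0.01      # events per month
    censor_rate: float = 0.005         # censorings per month
    admin_cutoff: float = 120.0        # months
    subtype_props: dict = field(default_factory=lambda: {
        "basal": 0.15, "luminal_A": 0.35, "luminal_B": 0.20,
        "HER2": 0.15, "normal_like": 0.15,
    })
    covariate_mixing: float = 0.0      # weight tying clinical covariates to risk score
    seed: int | None = None

    def __post_init__(self):
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if len(self.risk_genes) != len(self.per_gene_log_hr):
            raise ValueError("risk_genes and per_gene_log_hr lengths differ")
        total = sum(self.subtype_props.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"subtype_props must sum to 1, got {total}")

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_ids(n_genes: int) -> list:
    return [f"G{i:05d}" for i in range(n_genes)]


def simulate_two_class_expression(
    n_genes: int,
    n_per_class: int,
    n_de: int,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    seed=None,
) -> tuple[ExpressionMatrix, TwoClassSimTruth]:
    """Simulate a two-class log2-ratio matrix with planted DE genes.

    ``n_de`` genes (chosen at random) receive a class-mean difference of
    ``effect_size`` log2 units with a random sign; all other genes have
    equal class means.  Residuals are iid Gaussian with ``noise_sd``.

    Returns the matrix (samples labeled ``migratory`` / ``average``,
    effects planted as migratory minus average) and the planted truth.
    """
    if n_genes <= 0 or n_de < 0 or n_per_class <= 0:
        raise ValueError("counts must be positive (n_de may be 0)")
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")

    rng = as_generator(seed)
    genes = _gene_ids(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effects = np.zeros(n_genes)
    effects[de_idx] = signs * effect_size
    flags = np.zeros(n_genes, dtype=int)
    flags[de_idx] = 1

    # symmetric split of the shift around a zero gene baseline
    mean_mig = effects / 2.0
    mean_avg = -effects / 2.0
    noise = rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_class))
    values = np.concatenate(
        [mean_mig[:, None] + noise[:, :n_per_class],
         mean_avg[:, None] + noise[:, n_per_class:]],
        axis=1,
    )
    samples = [f"migratory_{i+1}" for i in range(n_per_class)] + \
              [f"average_{i+1}" for i in range(n_per_class)]
    labels = pd.Series(
        ["migratory"] * n_per_class + ["average"] * n_per_class, index=samples
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        class_labels=labels,
    )
    truth = TwoClassSimTruth(
        de_flags=flags,
        de_log2_effects=effects,
        noise_sd=noise_sd,
        seed=seed if isinstance(seed, int) else None,
    )
    return matrix, truth


def _clinical_covariates(n: int, risk_score: np.ndarray, mixing: float,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariate marginals: grade uniform {1,2,3}, node
    Bernoulli(0.4), size log-normal with 2 cm median, ER Bernoulli(0.7).

    With ``mixing`` > 0 the latent propensity of each covariate is shifted
    by mixing * standardized risk score, inducing confounding on demand.
    """
    z = np.zeros(n)
    if mixing != 0.0 and np.std(risk_score) > 0:
        z = mixing * (risk_score - risk_score.mean()) / risk_score.std()

    grade_u = rng.random(n) + 0.15 * z
    grade = np.clip(np.ceil(np.clip(grade_u, 1e-9, 1 - 1e-9) * 3), 1, 3).astype(int)
    node = (rng.random(n) < np.clip(0.4 + 0.15 * z, 0.01, 0.99)).astype(int)
    size = np.exp(np.log(2.0) + 0.4 * rng.normal(size=n) + 0.2 * z)
    er = (rng.random(n) < np.clip(0.7 - 0.15 * z, 0.01, 0.99)).astype(int)
    return pd.DataFrame({
        "grade": grade, "node": node,
        "size_cm": np.round(size, 3), "er": er,
    })


def simulate_survival_cohort(
    n_patients: int,
    n_genes: int,
    truth: CohortSimTruth | None = None,
    seed=None,
) -> SurvivalCohort:
    """Simulate an expression + clinical cohort under proportional hazards.

    Expression is standard normal per gene.  Event times are exponential
    with rate baseline_hazard * exp(sum_g log_hr_g * x_gj); observed time
    is the minimum of event, censoring, and administrative cutoff times.
    Subtype labels are multinomial over ``truth.subtype_props``.

    ``seed`` overrides ``truth.seed`` when given; with an empty
    ``risk_genes`` list the cohort is a global null.
    """
    truth = truth if truth is not None else CohortSimTruth()
    if n_patients < 10:
        logger.warning("simulating a very small cohort (n=%d < 10)", n_patients)
    if n_patients <= 0 or n_genes <= 0:
        raise ValueError("counts must be positive")

    rng = as_generator(seed if seed is not None else truth.seed)
    genes = _gene_ids(n_genes)
    missing = [g for g in truth.risk_genes if g not in set(genes)]
    if missing:
        raise ValueError(f"risk_genes not in simulated gene universe: {missing[:5]}")

    X = rng.standard_normal((n_genes, n_patients))
    expr = pd.DataFrame(X, index=genes,
                        columns=[f"P{j:04d}" for j in range(n_patients)])

    lp = np.zeros(n_patients)
    if truth.risk_genes:
        coefs = np.asarray(truth.per_gene_log_hr, dtype=float)
        lp = coefs @ expr.loc[truth.risk_genes].to_numpy()

    rate = truth.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if truth.censor_rate > 0:
        t_cens = rng.exponential(1.0 / truth.censor_rate, size=n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    t_obs = np.minimum.reduce([t_event, t_cens, np.full(n_patients, truth.admin_cutoff)])
    event = (t_event <= np.minimum(t_cens, truth.admin_cutoff)).astype(int)
    t_obs = np.maximum(t_obs, 1e-6)  # guard strictly positive times

    subtype_labels = list(truth.subtype_props)
    probs = np.array([truth.subtype_props[s] for s in subtype_labels])
    subtype = rng.choice(subtype_labels, size=n_patients, p=probs)

    clin = _clinical_covariates(n_patients, lp, truth.covariate_mixing, rng)
    clin.insert(0, "time_months", np.round(t_obs, 4))
    clin.insert(1, "event", event)
    clin["subtype"] = subtype
    clin.index = expr.columns

    truth_record = truth.to_dict()
    truth_record["linear_predictor"] = lp.tolist()
    return SurvivalCohort(expression=expr, clinical=clin, truth=truth_record)
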