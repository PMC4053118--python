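import numpy as np
import pandas as pd
import pytest

from invasig import (ExpressionMatrix, GeneSignature,
                     simulate_survival_cohort, simulate_two_class_expression)
from invasig.synthetic import CohortSimTruth


@pytest.fixture
def two_class_matrix():
    """1000 genes, 4+4 samples, 50 planted DE genes at 2.0 log2 units."""
    matrix, truth = simulate_two_class_expression(
        n_genes=1000, n_per_class=4, n_de=50, effect_size=2.0,
        noise_sd=0.5, seed=20)
    return matrix, truth


@pytest.fixture
def null_cohort():
    """Global-null cohort: no gene carries hazard signal."""
    return simulate_survival_cohort(100, 200, CohortSimTruth(), seed=31)


@pytest.fixture
def planted_cohort():
    """Cohort where 20 genes jointly carry a unit-variance log-hazard score."""
    risk = [f"G{i:05d}" for i in range(20)]
    truth = CohortSimTruth(risk_genes=risk,
                           per_gene_log_hr=[1 / np.sqrt(20)] * 20)
    cohort = simulate_survival_cohort(250, 300, truth, seed=32)
    return cohort, GeneSignature.from_gene_ids(risk)


@pytest.fixture
def tiny_matrix():
    """Single-gene two-class fixture with hand-checkable values."""
    vals = pd.DataFrame([[1.0, 2, 3, 3, 4, 5]], index=["g1"],
                        columns=["a1", "a2", "a3", "b1", "b2", "b3"])
    labels = pd.Series(["c1"] * 3 + ["c2"] * 3, index=vals.columns)
    return ExpressionMatrix(vals, labels)
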