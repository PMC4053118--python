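"""Core data containers and their plain-text (TSV) serialization.

Three objects travel through the pipeline:

``ExpressionMatrix``
    genes x samples matrix of log2 ratios, optionally with pre-collapsing
    probe identifiers and a two-level class label per sample.
``GeneSignature``
    an ordered gene list with a +/-1 direction and a linear-scale fold
    change per gene.
``SurvivalCohort``
    per-patient expression plus a clinical table (time, event, grade,
    nodal status, tumor size, ER status, intrinsic subtype).

All on-disk formats are uncompressed TSV: expression as genes-as-rows with
a header of sample ids, signatures as four columns, clinical tables with a
fixed schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = [
    "patient_id",
    "time_months",
    "event",
    "grade",
    "node",
    "size_cm",
    "er",
    "subtype",
]

SUBTYPES = ["basal", "luminal_A", "luminal_B", "HER2", "normal_like"]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-ratio matrix.

    ``values`` is indexed by gene (or probe) identifier with sample ids as
    columns.  ``class_labels`` maps sample id -> class for two-class
    designs; ``probe_ids`` is set while rows are still probes (before
    collapsing to genes).
    """

    values: pd.DataFrame
    class_labels: pd.Series | None = None
    probe_ids: pd.Index | None = None

    def __post_init__(self):
        if self.class_labels is not None:
            self.class_labels = pd.Series(self.class_labels)
            missing = [s for s in self.values.columns if s not in self.class_labels.index]
            if missing:
                raise ValueError(f"class_labels missing for samples: {missing[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> list:
        """The two class levels, in sorted order."""
        if self.class_labels is None:
            raise ValueError("matrix carries no class labels")
        levels = sorted(pd.unique(self.class_labels.loc[self.values.columns]))
        if len(levels) != 2:
            raise ValueError(f"expected exactly two classes, found {levels}")
        return levels

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, labels: "pd.Series | dict | None" = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lab = pd.Series(labels) if labels is not None else None
        return cls(values=df, class_labels=lab)


@dataclass
class GeneSignature:
    """An ordered gene list with direction (+1 up, -1 down) and fold change.

    ``table`` columns: gene_id, direction, fold_change, rank.  Direction is
    +1 iff the linear fold change of class-of-interest over reference
    exceeds 1.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"gene_id", "direction", "fold_change", "rank"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"signature table missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("signature gene_ids must be unique")
        self.table = self.table.reset_index(drop=True)

    @property
    def gene_ids(self) -> list:
        return list(self.table["gene_id"])

    @property
    def directions(self) -> np.ndarray:
        return self.table["direction"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneSignature":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_gene_ids(cls, gene_ids, directions=None, fold_changes=None) -> "GeneSignature":
        gene_ids = list(gene_ids)
        n = len(gene_ids)
        d = np.ones(n) if directions is None else np.asarray(directions, dtype=float)
        f = np.where(d > 0, 2.0, 0.5) if fold_changes is None else np.asarray(fold_changes, dtype=float)
        return cls(pd.DataFrame({
            "gene_id": gene_ids,
            "direction": d.astype(int),
            "fold_change": f,
            "rank": np.arange(1, n + 1),
        }))


@dataclass
class SurvivalCohort:
    """Per-patient expression plus clinical follow-up.

    ``expression`` is genes x patients; ``clinical`` is indexed by
    patient_id with columns time_months (> 0), event ({0,1}; 1 =
    metastasis/recurrence), grade ({1,2,3}), node ({0,1}), size_cm, er
    ({0,1}) and subtype.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.expression.columns.equals(self.clinical.index):
            if set(self.expression.columns) != set(self.clinical.index):
                raise ValueError("expression columns and clinical index disagree")
            self.clinical = self.clinical.loc[self.expression.columns]
        t = self.clinical["time_months"].to_numpy()
        if (t <= 0).any():
            raise ValueError("time_months must be positive")
        ev = self.clinical["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def patient_ids(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def time(self) -> np.ndarray:
        return self.clinical["time_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=int)

    def subset_patients(self, patient_ids) -> "SurvivalCohort":
        patient_ids = list(patient_ids)
        return SurvivalCohort(
            expression=self.expression[patient_ids],
            clinical=self.clinical.loc[patient_ids],
            truth=self.truth,
        )

    def drop_subtype(self, subtype: str) -> "SurvivalCohort":
        keep = self.clinical.index[self.clinical["subtype"] != subtype]
        return self.subset_patients(keep)

    def to_tsv(self, expr_path, clinical_path) -> None:
        df = self.expression.copy()
        df.index.name = "gene_id"
        df.to_csv(expr_path, sep="\t")
        out = self.clinical.reset_index().rename(columns={"index": "patient_id"})
        if "patient_id" not in out.columns:
            out.insert(0, "patient_id", self.clinical.index)
        out[CLINICAL_COLUMNS].to_csv(clinical_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, expr_path, clinical_path) -> "SurvivalCohort":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        clin = pd.read_csv(clinical_path, sep="\t").set_index("patient_id")
        clin.index = clin.index.astype(str)
        expr.columns = expr.columns.astype(str)
        return cls(expression=expr, clinical=clin)
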