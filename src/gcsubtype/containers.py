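"""Core data containers shared across the pipeline.

The substrate of every stage is a genes x samples expression matrix with
per-sample annotations (tissue type and cohort), carried on either the
linear or the log2 scale; an explicit scale flag prevents silent double
transforms.  Subtype labels, gene signatures and clinical tables are thin
wrappers around pandas objects with the invariants each stage relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MP = "MP"
EP = "EP"
SUBTYPES = (MP, EP)
TISSUE_TYPES = ("tumor", "normal", "outgroup")
SCALES = ("log2", "linear")

#: columns of the clinical table written/read by this package
CLINICAL_COLUMNS = [
    "sample_id",
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
    "stage",
    "distant_metastasis",
    "age",
    "sex",
    "chemo",
    "lauren",
    "tissue_type",
    "cohort",
]

STAGES = ("I", "II", "III", "IV")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    sample_annotations
        DataFrame indexed by sample id with at least ``tissue_type``
        (tumor / normal / outgroup) and ``cohort`` columns.  If omitted,
        every sample is annotated as a tumor of cohort "0".
    scale
        Either ``"log2"`` or ``"linear"``.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame | None = None
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if self.sample_annotations is None:
            self.sample_annotations = pd.DataFrame(
                {"tissue_type": "tumor", "cohort": "0"}, index=self.values.columns
            )
        else:
            missing = self.values.columns.difference(self.sample_annotations.index)
            if len(missing):
                raise ValidationError(f"samples lack annotations: {list(missing)[:5]}")
            self.sample_annotations = self.sample_annotations.loc[self.values.columns]
            bad = set(self.sample_annotations["tissue_type"]) - set(TISSUE_TYPES)
            if bad:
                raise ValidationError(f"unknown tissue types: {bad}")

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

    def samples_of_type(self, tissue_type: str) -> list[str]:
        ann = self.sample_annotations
        return list(ann.index[ann["tissue_type"] == tissue_type])

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples_of_type("tumor")

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[sample_ids],
            self.sample_annotations.loc[sample_ids],
            scale=self.scale,
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)], self.sample_annotations, scale=self.scale
        )

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values,
            self.sample_annotations.loc[values.columns],
            scale=self.scale if scale is None else scale,
        )

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return self.with_values(np.exp2(self.values), scale="linear")


@dataclass
class SubtypeLabels:
    """MP/EP label per tumor sample, optionally with a posterior P(MP)."""

    labels: pd.Series
    posterior: pd.Series | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(SUBTYPES)
        if bad:
            raise ValidationError(f"labels must be in {SUBTYPES}, got {bad}")
        if self.posterior is not None:
            self.posterior = self.posterior.reindex(self.labels.index)
            if self.posterior.isna().any():
                raise ValidationError("posterior missing for some labeled samples")
            if ((self.posterior < 0) | (self.posterior > 1)).any():
                raise ValidationError("posteriors must lie in [0, 1]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    def samples(self, subtype: str) -> list[str]:
        return list(self.labels.index[self.labels == subtype])

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class GeneSignature:
    """Signature genes with t-statistic weights (sign = MP direction).

    ``table`` is indexed by gene id with columns ``weight`` (the training
    MP-vs-EP t statistic), ``log2_fold_change`` (MP minus EP) and
    ``p_value``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"weight", "log2_fold_change", "p_value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"signature table missing columns: {missing}")
        if len(self.table):
            w = self.table["weight"].to_numpy(float)
            if not np.all(np.isfinite(w)) or np.any(w == 0):
                raise ValidationError("signature weights must be finite and nonzero")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GeneSignature":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))

    def to_json(self, path=None):
        payload = {
            "genes": {
                g: {
                    "weight": float(r["weight"]),
                    "log2_fold_change": float(r["log2_fold_change"]),
                    "p_value": float(r["p_value"]),
                }
                for g, r in self.table.iterrows()
            }
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, payload) -> "GeneSignature":
        if not isinstance(payload, dict):
            payload = json.loads(Path(payload).read_text())
        table = pd.DataFrame.from_dict(payload["genes"], orient="index")
        table.index.name = "gene_id"
        return cls(table)


# ---------------------------------------------------------------------------
# Tab-delimited I/O (first column gene id, header row of sample ids)
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression(path, annotations: pd.DataFrame | None = None,
                    scale: str = "log2") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return ExpressionMatrix(values, annotations, scale=scale)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    validate_clinical(clinical)
    clinical[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    validate_clinical(clinical)
    return clinical


def validate_clinical(clinical: pd.DataFrame) -> None:
    """Schema check; survival/stage fields are required for tumor rows only
    (non-tumor rows carry sample annotations and may hold NaN there)."""
    missing = set(CLINICAL_COLUMNS) - set(clinical.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    if clinical["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in clinical table")
    bad_tissue = set(clinical["tissue_type"]) - set(TISSUE_TYPES)
    if bad_tissue:
        raise ValidationError(f"unknown tissue types: {bad_tissue}")
    tumors = clinical.loc[clinical["tissue_type"] == "tumor"]
    for col in ("os_time", "rfs_time"):
        if tumors[col].isna().any() or (tumors[col] <= 0).any():
            raise ValidationError(f"{col} must be strictly positive")
    for col in ("os_event", "rfs_event", "chemo", "distant_metastasis"):
        if not tumors[col].isin([0, 1]).all():
            raise ValidationError(f"{col} must be binary 0/1")
    if not tumors["stage"].isin(STAGES).all():
        raise ValidationError(f"stage must be one of {STAGES}")


def annotations_from_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    ann = clinical.set_index("sample_id")[["tissue_type", "cohort"]]
    ann["cohort"] = ann["cohort"].astype(str)
    return ann
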