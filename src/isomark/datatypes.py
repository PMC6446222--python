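"""Core in-memory containers for expression and essentiality data.

All containers are thin, validated wrappers around pandas DataFrames.
Features (transcripts, and later derived gene aggregates) sit in rows;
cell-line samples sit in columns.  Essentiality matrices hold DEMETER-style
scores (more negative = more essential) with KD target genes in rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSCRIPT = "transcript"
GENE = "gene"

#: columns every feature annotation table must carry
ANNOTATION_COLUMNS = ("parent_gene", "biotype", "level")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what}: {dupes[:5]}")


@dataclass
class ExpressionSet:
    """Annotated TPM matrix (features x samples).

    ``annotation`` is indexed by feature_id with columns ``parent_gene``,
    ``biotype`` and ``level`` (``transcript`` or ``gene``).  Gene-level rows
    are derived aggregates whose feature_id equals their parent_gene.
    """

    tpm: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.tpm.index, "feature_id")
        _check_unique(self.tpm.columns, "sample_id")
        vals = self.tpm.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("expression matrix contains missing values")
        if (vals < 0).any():
            bad = self.tpm.index[(vals < 0).any(axis=1)][0]
            raise ValueError(f"negative TPM for feature {bad!r}; TPM must be >= 0")
        missing_ann = self.tpm.index.difference(self.annotation.index)
        if len(missing_ann):
            raise ValueError(f"no annotation for feature(s): {missing_ann[:5].tolist()}")
        # keep annotation aligned to the matrix rows
        self.annotation = self.annotation.loc[self.tpm.index, list(ANNOTATION_COLUMNS)]
        tr = self.annotation["level"] == TRANSCRIPT
        if (self.annotation.loc[tr, "parent_gene"].astype(str) == "").any():
            raise ValueError("transcript feature with empty parent_gene")
        ge = self.annotation["level"] == GENE
        mism = self.annotation.index[ge] != self.annotation.loc[ge, "parent_gene"]
        if np.asarray(mism).any():
            raise ValueError("gene-level feature_id must equal its parent_gene")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.annotation.index[self.annotation["level"] == TRANSCRIPT]

    @property
    def gene_ids(self) -> pd.Index:
        return self.annotation.index[self.annotation["level"] == GENE]

    def subset_samples(self, sample_ids) -> "ExpressionSet":
        return ExpressionSet(self.tpm.loc[:, list(sample_ids)], self.annotation)

    def subset_features(self, feature_ids) -> "ExpressionSet":
        return ExpressionSet(self.tpm.loc[list(feature_ids)], self.annotation)


@dataclass
class EssentialityMatrix:
    """DEMETER-style essentiality scores, KD genes x samples; NaN = missing."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "kd_gene")
        _check_unique(self.scores.columns, "sample_id")
        self.scores = self.scores.astype(float)
        self.scores.index.name = "kd_gene"
        self.scores.columns.name = None

    @property
    def kd_gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_missing(self) -> int:
        return int(self.scores.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "EssentialityMatrix":
        return EssentialityMatrix(self.scores.loc[:, list(sample_ids)])


@dataclass
class SensitivityMatrix:
    """Dichotomized essentiality: 1 = sensitive (score < threshold), 0 = resistant."""

    calls: pd.DataFrame
    threshold: float

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("sensitivity calls must be 0/1 with no missing values")
        self.calls = self.calls.astype(np.int8)

    def labels(self, kd_gene: str, sample_ids) -> pd.Series:
        """Boolean sensitive/resistant labels for one KD target over given samples."""
        return self.calls.loc[kd_gene, list(sample_ids)].astype(bool)


@dataclass
class LogExpressionSet:
    """log2(TPM + offset) matrix sharing the ExpressionSet annotation."""

    logexpr: pd.DataFrame
    offset: float
    annotation: pd.DataFrame = field(repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.logexpr.columns)
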