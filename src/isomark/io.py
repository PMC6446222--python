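"""Readers/writers for the tabular interchange formats and sample alignment.

Formats (all UTF-8, '.' decimal separator):

* ``expression.tsv``   — header ``feature_id<TAB>sample1<TAB>...``; TPM values.
* ``annotation.tsv``   — ``feature_id<TAB>parent_gene<TAB>biotype``.
* ``essentiality.csv`` — ``kd_gene,sample1,...``; blank or ``NA`` cells are
  missing values (written back as ``NA``).
* ``metadata.tsv``     — ``sample_id<TAB>primary_site<TAB>subtype``.

Both matrices are oriented features/KD-genes in rows, samples in columns.
Sample matching is by exact string id.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import TRANSCRIPT, EssentialityMatrix, ExpressionSet

NA_VALUES = ["", "NA"]

#: minimum number of shared samples for any downstream two-group test
MIN_SHARED_SAMPLES = 4


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, annotation_path) -> ExpressionSet:
    """Read a transcript-level TPM matrix plus its feature annotation."""
    tpm = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    tpm.index = tpm.index.astype(str)
    ann = pd.read_csv(annotation_path, sep=_sep_for(annotation_path), dtype=str)
    required = {"feature_id", "parent_gene", "biotype"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    ann = ann.set_index("feature_id")
    if ann.index.duplicated().any():
        raise ValueError("duplicated feature_id in annotation")
    ann["level"] = TRANSCRIPT
    missing = tpm.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"no annotation for feature(s): {missing[:5].tolist()}")
    return ExpressionSet(tpm.astype(float), ann.loc[tpm.index])


def read_essentiality(path) -> EssentialityMatrix:
    """Read a KD-genes x samples score table; blank/NA cells become missing."""
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicated KD gene row id: {dup!r}")
    scores = raw.apply(lambda col: pd.to_numeric(col.where(~col.isin(NA_VALUES)),
                                                 errors="coerce"))
    bad = scores.isna() & ~raw.isin(NA_VALUES)
    if bad.to_numpy().any():
        i, j = next(zip(*bad.to_numpy().nonzero()))
        raise ValueError(
            f"non-numeric cell at row {raw.index[i]!r}, column {raw.columns[j]!r}: "
            f"{raw.iloc[i, j]!r}")
    return EssentialityMatrix(scores)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, primary_site, subtype)."""
    meta = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("")
    required = {"sample_id", "primary_site", "subtype"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in metadata")
    if (meta["primary_site"] == "").any():
        raise ValueError("empty primary_site in metadata")
    return meta.reset_index(drop=True)


def write_expression(expr: ExpressionSet, path, annotation_path=None) -> None:
    expr.tpm.to_csv(path, sep=_sep_for(path), index_label="feature_id")
    if annotation_path is not None:
        ann = expr.annotation.loc[expr.annotation["level"] == TRANSCRIPT,
                                  ["parent_gene", "biotype"]]
        ann.to_csv(annotation_path, sep=_sep_for(annotation_path),
                   index_label="feature_id")


def write_essentiality(ess: EssentialityMatrix, path) -> None:
    ess.scores.to_csv(path, sep=_sep_for(path), index_label="kd_gene", na_rep="NA")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep=_sep_for(path), index=False)


def align_samples(expr: ExpressionSet, ess: EssentialityMatrix,
                  meta: pd.DataFrame):
    """Restrict all three inputs to their shared samples, in identical order.

    Order follows the expression matrix's column order.  Fewer than
    MIN_SHARED_SAMPLES shared ids is an error: a two-group comparison needs
    at least two samples per group.
    """
    shared = set(expr.sample_ids) & set(ess.sample_ids) & set(meta["sample_id"])
    order = [s for s in expr.sample_ids if s in shared]
    if len(order) < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"only {len(order)} shared sample(s) between expression, "
            f"essentiality and metadata; need >= {MIN_SHARED_SAMPLES}")
    meta_aligned = meta.set_index("sample_id").loc[order].reset_index()
    return expr.subset_samples(order), ess.subset_samples(order), meta_aligned


def select_cohort(meta: pd.DataFrame, sites=(), subtypes=()) -> list[str]:
    """Select sample ids whose primary site or subtype is requested (union)."""
    sites, subtypes = set(sites), set(subtypes)
    if not sites and not subtypes:
        raise ValueError("no sites or subtypes requested")
    keep = meta["primary_site"].isin(sites) | meta["subtype"].isin(subtypes)
    ids = meta.loc[keep, "sample_id"].tolist()
    if not ids:
        raise ValueError("empty cohort: no sample matches the requested "
                         "sites/subtypes")
    return ids
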