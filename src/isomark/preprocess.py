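"""Preprocessing: imputation, dichotomization, gene aggregation, filtering.

The essentiality matrix is completed by k-nearest-neighbour averaging and
then dichotomized at a DEMETER threshold (default -2, strict ``<``) into
sensitive (1) / resistant (0) calls.  Transcript TPM is aggregated to gene
TPM by summation (TPM is additive across a gene's transcripts), expression
is log2(TPM + offset) transformed, and features are filtered in two stages:
drop features with zero TPM in every loaded sample, then keep features whose
mean TPM over the selected cohort reaches a quantile of all survivors'
cohort means, separately within transcript- and gene-level rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .datatypes import (GENE, TRANSCRIPT, EssentialityMatrix, ExpressionSet,
                        LogExpressionSet, SensitivityMatrix)

DEFAULT_DEMETER_THRESHOLD = -2.0
DEFAULT_KNN_K = 10
DEFAULT_LOG_OFFSET = 1.0
DEFAULT_QUANTILE = 0.5


def knn_impute(ess: EssentialityMatrix, k: int = DEFAULT_KNN_K) -> EssentialityMatrix:
    """Impute missing scores from the k nearest KD-gene rows.

    Distance between rows is Euclidean over mutually observed columns,
    scaled by the fraction of columns observed; a missing entry becomes the
    mean of that column's values over the k nearest rows that observe it.
    Observed entries are never modified.
    """
    scores = ess.scores
    all_missing = scores.isna().all(axis=1)
    if all_missing.any():
        gene = scores.index[all_missing][0]
        raise ValueError(f"KD gene {gene!r} has no observed essentiality score")
    if k < 1 or k > len(scores.index) - 1:
        raise ValueError(f"k must be in [1, {len(scores.index) - 1}], got {k}")
    if not scores.isna().to_numpy().any():
        return EssentialityMatrix(scores.copy())
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(scores.to_numpy())
    out = pd.DataFrame(filled, index=scores.index, columns=scores.columns)
    # observed values pass through the imputer untouched; restore exactly
    out = out.where(scores.isna(), scores)
    return EssentialityMatrix(out)


def dichotomize(ess: EssentialityMatrix,
                thr: float = DEFAULT_DEMETER_THRESHOLD) -> SensitivityMatrix:
    """Call each (KD gene, sample) sensitive iff score < thr (strict)."""
    if ess.scores.isna().to_numpy().any():
        raise ValueError("essentiality matrix has missing values; "
                         "impute first (knn_impute)")
    calls = (ess.scores < thr).astype(np.int8)
    return SensitivityMatrix(calls, threshold=float(thr))


def aggregate_gene_tpm(expr: ExpressionSet) -> ExpressionSet:
    """Append one gene-level row per parent gene (sum of its transcripts' TPM)."""
    tr_ids = expr.transcript_ids
    tr_tpm = expr.tpm.loc[tr_ids]
    parents = expr.annotation.loc[tr_ids, "parent_gene"]
    gene_tpm = tr_tpm.groupby(parents.values).sum()
    gene_tpm.index = gene_tpm.index.astype(str)
    clash = gene_tpm.index.intersection(tr_ids)
    if len(clash):
        raise ValueError(f"gene id collides with a transcript id: {clash[0]!r}")
    gene_ann = pd.DataFrame(
        {"parent_gene": gene_tpm.index, "biotype": "gene_aggregate",
         "level": GENE}, index=gene_tpm.index)
    tpm = pd.concat([tr_tpm, gene_tpm])
    ann = pd.concat([expr.annotation.loc[tr_ids], gene_ann])
    return ExpressionSet(tpm, ann)


def log_transform(expr: ExpressionSet,
                  offset: float = DEFAULT_LOG_OFFSET) -> LogExpressionSet:
    """Return log2(TPM + offset); the default offset 1 keeps zeros at 0."""
    if offset <= 0:
        raise ValueError(f"offset must be > 0, got {offset}")
    return LogExpressionSet(np.log2(expr.tpm + offset), float(offset),
                            expr.annotation)


def filter_features(expr: ExpressionSet, cohort,
                    quantile: float = DEFAULT_QUANTILE,
                    return_table: bool = False):
    """Two-stage expression filter; returns the kept feature ids.

    Stage 1 drops features with zero TPM in every loaded sample (cohort and
    background alike).  Stage 2 keeps survivors whose mean TPM over the
    cohort is >= the ``quantile`` quantile (linear interpolation) of all
    survivors' cohort means, applied separately per feature level.
    With ``return_table=True`` also returns the per-feature decision table.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    missing = set(cohort) - set(expr.sample_ids)
    if missing:
        raise ValueError(f"cohort sample(s) not in expression data: "
                         f"{sorted(missing)[:5]}")
    nonzero = expr.tpm.gt(0).any(axis=1)
    cohort_mean = expr.tpm[cohort].mean(axis=1)
    kept = pd.Series(False, index=expr.tpm.index)
    for level in (TRANSCRIPT, GENE):
        lvl = (expr.annotation["level"] == level) & nonzero
        if not lvl.any():
            continue
        means = cohort_mean[lvl]
        cut = float(np.quantile(means.to_numpy(), quantile))
        kept[means.index[means >= cut]] = True
    kept_ids = expr.tpm.index[kept]
    if return_table:
        table = pd.DataFrame({"kept": kept, "cohort_mean": cohort_mean,
                              "level": expr.annotation["level"]})
        table.index.name = "feature_id"
        return kept_ids, table
    return kept_ids
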