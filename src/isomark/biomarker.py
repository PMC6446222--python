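"""Best-marker selection, ranking, AUC and summary statistics.

For each (essential KD gene, candidate parent gene) pair the gene-level
lfdr is compared with the minimum lfdr among the gene's transcripts; the
smaller wins and decides whether the best biomarker is the gene or one of
its isoforms.  Records are then filtered at significance thresholds and
ranked.  Rank-based (Mann-Whitney) AUC quantifies how well the selected
marker's expression separates sensitive from resistant lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import GENE, TRANSCRIPT

#: lfdr difference below which gene and transcript are considered tied
TIE_EPS = 1e-12

DEFAULT_MAX_P = 1e-4
DEFAULT_MIN_ABS_LOGFC = 2.0
DEFAULT_MAX_LFDR = 0.1

RANKING_COLUMNS = ["Gene_Ess", "Gene_bmkr", "Transcript_bmkr", "tr", "logFC",
                   "Lfdr", "P", "Group_bmkr", "AUC", "AUC_raw"]


def auc(values, sensitive, logfc_sign: float = 1.0) -> tuple[float, float]:
    """Rank-based AUC of expression classifying sensitive vs resistant lines.

    Returns (oriented, raw).  ``raw`` is the Mann-Whitney concordance
    P(sensitive sample expresses higher than resistant sample), with
    midranks for ties.  ``oriented`` flips it when the marker's logFC is
    negative, so a marker perfectly consistent with its fold-change
    direction scores 1.0.
    """
    values = np.asarray(values, dtype=float)
    sensitive = np.asarray(sensitive, dtype=bool)
    n_s, n_r = int(sensitive.sum()), int((~sensitive).sum())
    if n_s == 0 or n_r == 0:
        raise ValueError("AUC needs at least one sample in each class")
    ranks = rankdata(values)
    u = ranks[sensitive].sum() - n_s * (n_s + 1) / 2.0
    raw = float(u / (n_s * n_r))
    oriented = raw if logfc_sign >= 0 else 1.0 - raw
    return oriented, raw


def select_best(tests_kd: pd.DataFrame, annotation: pd.DataFrame,
                parent_gene: str, kd_gene: str) -> dict | None:
    """Pick the gene-vs-transcript best marker record for one parent gene.

    ``tests_kd`` is the lfdr-annotated test table for a single KD target,
    indexed by feature_id.  Ties (within TIE_EPS) resolve to the gene-level
    marker.  Returns None when no feature of the parent gene was tested.
    """
    gene_row = tests_kd.loc[[parent_gene]] if parent_gene in tests_kd.index \
        else tests_kd.iloc[0:0]
    gene_row = gene_row[gene_row["level"] == GENE]
    tr_ids = annotation.index[(annotation["parent_gene"] == parent_gene)
                              & (annotation["level"] == TRANSCRIPT)]
    tr_rows = tests_kd.loc[tests_kd.index.intersection(tr_ids)]
    tr_rows = tr_rows[tr_rows["level"] == TRANSCRIPT]
    if gene_row.empty and tr_rows.empty:
        return None

    best_tr = None
    if not tr_rows.empty:
        order = tr_rows.sort_values(["lfdr", "p"], kind="mergesort")
        best_tr = order.iloc[0]
    if gene_row.empty:
        chosen, group = best_tr, TRANSCRIPT
    elif best_tr is None or \
            best_tr["lfdr"] >= gene_row.iloc[0]["lfdr"] - TIE_EPS:
        chosen, group = gene_row.iloc[0], GENE
    else:
        chosen, group = best_tr, TRANSCRIPT
    return {
        "Gene_Ess": kd_gene,
        "Gene_bmkr": parent_gene,
        "Transcript_bmkr": chosen.name if group == TRANSCRIPT else "",
        "tr": int(len(tr_rows)),
        "logFC": float(chosen["logfc"]),
        "Lfdr": float(chosen["lfdr"]),
        "P": float(chosen["p"]),
        "Group_bmkr": "Transcript" if group == TRANSCRIPT else "Gene",
        "marker_feature": chosen.name,
    }


def rank_and_filter(records: pd.DataFrame,
                    max_p: float = DEFAULT_MAX_P,
                    min_abs_logfc: float = DEFAULT_MIN_ABS_LOGFC,
                    max_lfdr: float = DEFAULT_MAX_LFDR) -> pd.DataFrame:
    """Keep records with P < max_p, |logFC| > min_abs_logfc, Lfdr < max_lfdr.

    Sorted by Lfdr ascending, then |logFC| descending, then marker id.
    """
    if records.empty:
        return records.copy()
    keep = (records["P"] < max_p) \
        & (records["logFC"].abs() > min_abs_logfc) \
        & (records["Lfdr"] < max_lfdr)
    out = records.loc[keep].copy()
    out["_abs_logfc"] = out["logFC"].abs()
    tie_col = "marker_feature" if "marker_feature" in out.columns else "Gene_bmkr"
    out = out.sort_values(["Lfdr", "_abs_logfc", tie_col],
                          ascending=[True, False, True], kind="mergesort")
    return out.drop(columns="_abs_logfc").reset_index(drop=True)


def transcript_proportion(records: pd.DataFrame) -> float:
    """Fraction of one essential gene's passing biomarkers that are transcripts."""
    if records.empty:
        raise ValueError("no passing biomarkers; proportion undefined")
    return float((records["Group_bmkr"] == "Transcript").mean())


def transcript_proportion_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-essential-gene transcript-biomarker proportions (empty genes excluded)."""
    rows = [(kd, len(sub), transcript_proportion(sub))
            for kd, sub in records.groupby("Gene_Ess", sort=True) if len(sub)]
    return pd.DataFrame(rows, columns=["Gene_Ess", "n_biomarkers",
                                       "transcript_proportion"])


def biotype_summary(records: pd.DataFrame, annotation: pd.DataFrame
                    ) -> tuple[dict[str, float], dict[str, float]]:
    """Biotype proportions among transcript biomarkers and in the annotation.

    Returns (marker proportions, reference proportions over the whole
    loaded transcript annotation).  Both sum to 1 over observed biotypes;
    the marker map is empty when there are no transcript biomarkers.
    """
    tr_ann = annotation[annotation["level"] == TRANSCRIPT]
    general = tr_ann["biotype"].value_counts(normalize=True).to_dict()
    tr_records = records[records["Group_bmkr"] == "Transcript"]
    if tr_records.empty:
        return {}, general
    biotypes = tr_ann.loc[tr_records["Transcript_bmkr"], "biotype"]
    markers = biotypes.value_counts(normalize=True).to_dict()
    return markers, general
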