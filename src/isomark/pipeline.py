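"""Orchestration of the three-step workflow.

select cohort -> find essential genes -> predict biomarkers, as composable
library functions plus file-based runners that write the result tables and
a run manifest.  The analysis itself is deterministic; randomness exists
only in the synthetic-data generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarker as bm
from . import essential, io, lfdr, modstats, preprocess
from .datatypes import (GENE, TRANSCRIPT, EssentialityMatrix, ExpressionSet,
                        SensitivityMatrix)

logger = logging.getLogger("isomark")


@dataclass
class RunConfig:
    """All inputs and thresholds of one run; echoed into the manifest."""

    expression: str = ""
    annotation: str = ""
    essentiality: str = ""
    metadata: str = ""
    outdir: str = "isomark_run"
    sites: list[str] = field(default_factory=list)
    subtypes: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    all_passing: bool = True
    # preprocessing
    knn_k: int = preprocess.DEFAULT_KNN_K
    demeter_thr: float = preprocess.DEFAULT_DEMETER_THRESHOLD
    quantile: float = preprocess.DEFAULT_QUANTILE
    log_offset: float = preprocess.DEFAULT_LOG_OFFSET
    # essential-gene screen (case-study preset)
    min_frac_sensitive: float = essential.CASE_STUDY_PRESET["min_frac_sensitive"]
    min_enrichment: float = essential.CASE_STUDY_PRESET["min_enrichment"]
    expr_tpm_thr: float = essential.CASE_STUDY_PRESET["expr_tpm_thr"]
    min_frac_expressed: float = essential.CASE_STUDY_PRESET["min_frac_expressed"]
    enrichment_definition: str = "ratio"
    # biomarker prediction
    min_group_size: int = lfdr.DEFAULT_MIN_GROUP_SIZE
    max_p: float = bm.DEFAULT_MAX_P
    min_abs_logfc: float = bm.DEFAULT_MIN_ABS_LOGFC
    max_lfdr: float = bm.DEFAULT_MAX_LFDR
    seed: int = 0


@dataclass
class FindEssentialResult:
    records: pd.DataFrame
    sens: SensitivityMatrix
    ess_imputed: EssentialityMatrix
    cohort: list[str]


@dataclass
class PredictResult:
    records: pd.DataFrame      # one per (KD target, parent gene), all candidates
    ranking: pd.DataFrame      # records passing the significance thresholds
    tests: pd.DataFrame        # every moderated-t test with lfdr
    groups: pd.DataFrame       # per (KD target, level) pi0 summary
    skipped: list[dict]        # targets without a valid two-group split
    kept_features: list[str]


def find_essential_genes(expr: ExpressionSet, ess: EssentialityMatrix,
                         cohort, *, knn_k: int = preprocess.DEFAULT_KNN_K,
                         demeter_thr: float = preprocess.DEFAULT_DEMETER_THRESHOLD,
                         **screen_kwargs) -> FindEssentialResult:
    """Impute -> dichotomize -> screen; expr/ess must already be aligned."""
    ess_imp = preprocess.knn_impute(ess, k=min(knn_k, len(ess.scores) - 1))
    sens = preprocess.dichotomize(ess_imp, demeter_thr)
    expr_aug = preprocess.aggregate_gene_tpm(expr)
    records = essential.screen(sens, expr_aug, cohort, **screen_kwargs)
    logger.info("screened %d KD genes; %d pass", len(records),
                int(records["passes"].sum()))
    return FindEssentialResult(records, sens, ess_imp, list(cohort))


def predict_biomarkers(expr: ExpressionSet, sens: SensitivityMatrix, cohort,
                       targets, *, quantile: float = preprocess.DEFAULT_QUANTILE,
                       log_offset: float = preprocess.DEFAULT_LOG_OFFSET,
                       min_group_size: int = lfdr.DEFAULT_MIN_GROUP_SIZE,
                       max_p: float = bm.DEFAULT_MAX_P,
                       min_abs_logfc: float = bm.DEFAULT_MIN_ABS_LOGFC,
                       max_lfdr: float = bm.DEFAULT_MAX_LFDR,
                       d0_override: float | None = None) -> PredictResult:
    """Genome-wide moderated-t + grouped lfdr biomarker prediction.

    For each KD target with >= 2 sensitive and >= 2 resistant cohort lines:
    test every filtered gene and transcript, squeeze variances per target
    (genes and transcripts pooled), then estimate lfdr within each
    (target, level) covariate group, pick the best marker per parent gene
    and apply the significance thresholds.
    """
    targets = list(targets)
    unknown = [t for t in targets if t not in sens.calls.index]
    if unknown:
        raise KeyError(f"unknown KD target(s): {unknown[:5]}")
    cohort = [s for s in expr.sample_ids if s in set(cohort)]

    expr_aug = preprocess.aggregate_gene_tpm(expr)
    kept = preprocess.filter_features(expr_aug, cohort, quantile)
    logexpr = preprocess.log_transform(expr_aug, log_offset)
    logger.info("feature filter kept %d/%d features", len(kept),
                len(expr_aug.feature_ids))

    tests_parts, skipped = [], []
    splits: dict[str, pd.Series] = {}
    for kd in targets:
        labels = sens.labels(kd, cohort)
        n_s = int(labels.sum())
        n_r = len(labels) - n_s
        if n_s < 2 or n_r < 2:
            reason = (f"{n_s} sensitive / {n_r} resistant cohort samples; "
                      "need >= 2 in each group")
            skipped.append({"kd_gene": kd, "reason": reason})
            logger.warning("skipping target %s: %s", kd, reason)
            continue
        splits[kd] = labels
        st = modstats.feature_stats(logexpr, labels, kept, kd_gene=kd)
        if d0_override is None:
            d0, s0_2 = modstats.squeeze_variances(
                st["s2"].to_numpy(), int(st["df_residual"].iloc[0]))
        else:
            pos = st.loc[st["s2"] > 0, "s2"]
            d0 = d0_override
            s0_2 = float(pos.mean()) if len(pos) else 1.0
        mt = modstats.moderated_t(st, d0, s0_2)
        mt.insert(0, "kd_gene", kd)
        tests_parts.append(mt)

    empty_records = pd.DataFrame(columns=bm.RANKING_COLUMNS)
    if not tests_parts:
        empty_tests = pd.DataFrame(
            columns=["kd_gene", "level", "p", "logfc", "lfdr"])
        return PredictResult(empty_records, empty_records.copy(), empty_tests,
                             pd.DataFrame(columns=lfdr.GROUP_COLUMNS),
                             skipped, list(kept))

    tests = pd.concat(tests_parts)
    tests, groups = lfdr.group_and_estimate(tests, min_group_size)
    logger.info("ran %d tests in %d covariate groups", len(tests), len(groups))

    ann = expr_aug.annotation
    parts = []
    for kd, tk in tests.groupby("kd_gene", sort=False):
        parts.append(_best_per_parent(tk, ann, kd))
    records_df = pd.concat(parts, ignore_index=True) if parts else empty_records
    if len(records_df):
        records_df = _attach_auc(records_df, logexpr, cohort, splits)
    ranking = bm.rank_and_filter(records_df, max_p, min_abs_logfc, max_lfdr)
    logger.info("%d candidate records, %d pass thresholds",
                len(records_df), len(ranking))
    return PredictResult(records_df, ranking, tests, groups, skipped,
                         list(kept))


def _best_per_parent(tk: pd.DataFrame, ann: pd.DataFrame,
                     kd: str) -> pd.DataFrame:
    """Vectorized gene-vs-transcript best-marker choice for one KD target.

    Equivalent to calling ``biomarker.select_best`` per parent gene:
    the smaller lfdr wins, ties within TIE_EPS go to the gene level.
    """
    tk = tk.copy()
    tk["parent"] = ann.loc[tk.index, "parent_gene"].to_numpy()
    tk = tk.reset_index(names="feature_id")
    genes = tk[tk["level"] == GENE].set_index("parent")
    trs = tk[tk["level"] == TRANSCRIPT]
    n_tr = trs.groupby("parent").size()
    best_tr = trs.sort_values(["lfdr", "p", "feature_id"], kind="mergesort") \
        .drop_duplicates("parent").set_index("parent")
    parents = genes.index.union(best_tr.index)
    g_lfdr = genes["lfdr"].reindex(parents)
    t_lfdr = best_tr["lfdr"].reindex(parents)
    take_tr = ((t_lfdr < g_lfdr - bm.TIE_EPS) | g_lfdr.isna()).to_numpy()
    bt, ge = best_tr.reindex(parents), genes.reindex(parents)

    def pick(col):
        return np.where(take_tr, bt[col].to_numpy(), ge[col].to_numpy())

    out = pd.DataFrame({
        "Gene_Ess": kd,
        "Gene_bmkr": parents,
        "Transcript_bmkr": np.where(take_tr, bt["feature_id"], ""),
        "tr": n_tr.reindex(parents).fillna(0).astype(int).to_numpy(),
        "logFC": pick("logfc").astype(float),
        "Lfdr": pick("lfdr").astype(float),
        "P": pick("p").astype(float),
        "Group_bmkr": np.where(take_tr, "Transcript", "Gene"),
        "marker_feature": pick("feature_id"),
    })
    return out


def _attach_auc(records: pd.DataFrame, logexpr, cohort,
                splits: dict[str, pd.Series]) -> pd.DataFrame:
    """Rank-based AUC of each selected marker, vectorized per KD target."""
    from scipy.stats import rankdata
    records = records.copy()
    auc_o = np.empty(len(records))
    auc_r = np.empty(len(records))
    for kd, idx in records.groupby("Gene_Ess", sort=False).indices.items():
        mask = splits[kd].to_numpy(dtype=bool)
        X = logexpr.logexpr.loc[records["marker_feature"].iloc[idx],
                                cohort].to_numpy()
        ranks = rankdata(X, axis=1)
        n_s, n_r = int(mask.sum()), int((~mask).sum())
        u = ranks[:, mask].sum(axis=1) - n_s * (n_s + 1) / 2.0
        raw = u / (n_s * n_r)
        logfc = records["logFC"].iloc[idx].to_numpy(dtype=float)
        auc_r[idx] = raw
        auc_o[idx] = np.where(logfc >= 0, raw, 1.0 - raw)
    records["AUC"] = auc_o
    records["AUC_raw"] = auc_r
    return records


# ---------------------------------------------------------------- file runners

def _resolve_cohort(meta: pd.DataFrame, config: RunConfig) -> list[str]:
    if config.sample_ids:
        known = set(meta["sample_id"])
        missing = [s for s in config.sample_ids if s not in known]
        if missing:
            raise ValueError(f"unknown cohort sample(s): {missing[:5]}")
        return list(config.sample_ids)
    return io.select_cohort(meta, config.sites, config.subtypes)


def _versions() -> dict:
    import sklearn
    import scipy
    from . import __version__
    return {"isomark": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__}


def _write_manifest(outdir: Path, config: RunConfig, extra: dict) -> None:
    manifest = {"config": asdict(config), "versions": _versions(), **extra}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))


def run_find_essential(config: RunConfig) -> pd.DataFrame:
    """File-based runner: align -> impute -> dichotomize -> screen."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(config.expression, config.annotation)
    ess = io.read_essentiality(config.essentiality)
    meta = io.read_metadata(config.metadata)
    expr, ess, meta = io.align_samples(expr, ess, meta)
    cohort = _resolve_cohort(meta, config)
    result = find_essential_genes(
        expr, ess, cohort, knn_k=config.knn_k, demeter_thr=config.demeter_thr,
        min_frac_sensitive=config.min_frac_sensitive,
        min_enrichment=config.min_enrichment,
        expr_tpm_thr=config.expr_tpm_thr,
        min_frac_expressed=config.min_frac_expressed,
        enrichment_definition=config.enrichment_definition)
    result.records.to_csv(outdir / "essential_genes.tsv", sep="\t", index=False)
    io.write_essentiality(result.ess_imputed, outdir / "essentiality_imputed.csv")
    (outdir / "cohort.txt").write_text("\n".join(cohort) + "\n")
    _write_manifest(outdir, config,
                    {"stage": "find_essential",
                     "n_cohort": len(cohort),
                     "n_passing": int(result.records["passes"].sum())})
    return result.records


def run_predict_biomarkers(config: RunConfig,
                           targets: list[str] | None = None) -> pd.DataFrame:
    """File-based runner for biomarker prediction.

    ``targets`` overrides the target list; otherwise the passing genes from
    a previous ``run_find_essential`` in the same output directory are used.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(config.expression, config.annotation)
    ess = io.read_essentiality(config.essentiality)
    meta = io.read_metadata(config.metadata)
    expr, ess, meta = io.align_samples(expr, ess, meta)
    cohort = _resolve_cohort(meta, config)
    ess_imp = preprocess.knn_impute(ess, k=min(config.knn_k,
                                               len(ess.scores) - 1))
    sens = preprocess.dichotomize(ess_imp, config.demeter_thr)

    if targets is None:
        targets = list(config.targets)
    if not targets:
        screen_path = outdir / "essential_genes.tsv"
        if not screen_path.exists():
            raise ValueError("no targets given and no essential_genes.tsv in "
                             f"{outdir}; run find-essential first")
        screened = pd.read_csv(screen_path, sep="\t")
        targets = screened.loc[screened["passes"], "kd_gene"].tolist()

    if not targets:
        ranking = pd.DataFrame(columns=bm.RANKING_COLUMNS)
        ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
        _write_manifest(outdir, config, {"stage": "predict_biomarkers",
                                         "targets": [], "skipped": []})
        return ranking

    result = predict_biomarkers(
        expr, sens, cohort, targets, quantile=config.quantile,
        log_offset=config.log_offset, min_group_size=config.min_group_size,
        max_p=config.max_p, min_abs_logfc=config.min_abs_logfc,
        max_lfdr=config.max_lfdr)
    ranking_cols = [c for c in bm.RANKING_COLUMNS
                    if c != "AUC_raw" and c in result.ranking.columns]
    result.ranking.loc[:, ranking_cols].to_csv(outdir / "ranking.tsv",
                                               sep="\t", index=False)
    result.records.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    result.groups.to_csv(outdir / "groups.tsv", sep="\t", index=False)
    bm.transcript_proportion_summary(result.ranking).to_csv(
        outdir / "transcript_proportions.tsv", sep="\t", index=False)
    markers, general = bm.biotype_summary(
        result.ranking, preprocess.aggregate_gene_tpm(expr).annotation)
    pd.DataFrame({"biotype": sorted(set(markers) | set(general)),
                  }).assign(
        marker_proportion=lambda d: d["biotype"].map(markers).fillna(0.0),
        general_proportion=lambda d: d["biotype"].map(general).fillna(0.0),
    ).to_csv(outdir / "biotype_proportions.tsv", sep="\t", index=False)
    _write_manifest(outdir, config,
                    {"stage": "predict_biomarkers", "targets": targets,
                     "skipped": result.skipped,
                     "n_tests": len(result.tests),
                     "n_passing": len(result.ranking)})
    return result.ranking
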