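"""Synthetic paired expression/essentiality data with planted structure.

The generator emulates the statistical structure the analysis assumes: a
cohort plus background of cell lines, a panel of KD target genes whose
DEMETER-style scores put designated samples below the -2 essentiality
threshold, and log-normal transcript TPM in which planted biomarkers shift
log2-expression by a fixed effect in the sensitive samples.  A transcript-
level effect raises one isoform and lowers a dominant sibling by the same
TPM amount, leaving the parent gene's total TPM unchanged — the isoform-
switch phenomenon that gene-level expression cannot see.

KD target ids are drawn from the simulated gene universe so screened KD
genes have gene-level expression rows; marker genes are assigned from the
remaining genes, one per planted-essential KD target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import TRANSCRIPT, EssentialityMatrix, ExpressionSet

BIOTYPES = ("protein_coding", "retained_intron", "nonsense_mediated_decay",
            "lincRNA", "processed_transcript", "antisense")
BIOTYPE_WEIGHTS = (0.50, 0.15, 0.10, 0.10, 0.10, 0.05)

GENE_LEVEL = "gene_level"
TRANSCRIPT_LEVEL = "transcript_level"
NULL = "null"

TRUTH_COLUMNS = ["kd_gene", "marker_gene", "marker_feature", "mode"]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a focused single-site cohort against a modest
    background: 14 cohort lines (a renal-sized cohort) plus 30 background
    lines, half of the cohort sensitive to each planted-essential KD
    target, log-normal TPM (log2 mean 3, sd 1.5), within-feature noise
    0.5 log2 units and a 4 log2-unit planted effect.
    """

    n_cohort: int = 14
    n_background: int = 30
    n_kd_genes: int = 20
    n_genes: int = 100
    tpg_min: int = 2          # transcripts per gene, uniform integer range
    tpg_max: int = 4
    frac_essential: float = 0.3
    frac_sensitive_in_cohort: float = 0.5
    background_sensitive_rate: float = 0.02
    effect_size: float = 4.0
    effect_mode: str = TRANSCRIPT_LEVEL
    noise_sd: float = 0.5
    missing_frac: float = 0.02
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    cohort_site: str = "kidney"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_sensitive_in_cohort", "background_sensitive_rate",
                     "missing_frac"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 <= self.frac_essential <= 1:
            raise ValueError("frac_essential must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_mode not in (GENE_LEVEL, TRANSCRIPT_LEVEL, NULL):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")
        if self.effect_mode == TRANSCRIPT_LEVEL and self.tpg_max < 2:
            raise ValueError("transcript_level effects need a compensating "
                             "sibling: transcripts_per_gene must allow >= 2")
        if self.tpg_min < 1 or self.tpg_max < self.tpg_min:
            raise ValueError("invalid transcripts-per-gene range")


@dataclass
class SimTruth:
    """Planted structure: marker table, essential KD targets, sensitivity classes."""

    markers: pd.DataFrame
    essential_kd: list[str] = field(default_factory=list)
    sensitive: pd.DataFrame | None = None   # bool, KD genes x samples


def _draw_scores(rng, sensitive_mask: np.ndarray) -> np.ndarray:
    """Scores from two normals (means -4 / 0, sd 1) clipped so that class
    membership under the strict < -2 rule is exact."""
    n_kd, n_samples = sensitive_mask.shape
    sens = np.clip(rng.normal(-4.0, 1.0, size=(n_kd, n_samples)), None, -2.2)
    res = np.clip(rng.normal(0.0, 1.0, size=(n_kd, n_samples)), -1.8, None)
    return np.where(sensitive_mask, sens, res)


def generate(config: SimConfig, _modes: list[str] | None = None
             ) -> tuple[ExpressionSet, EssentialityMatrix, pd.DataFrame, SimTruth]:
    """Generate (expression, essentiality, metadata, truth) for one config.

    ``_modes`` optionally assigns a per-planted-target effect mode (used by
    ``worked_fixture`` to mix gene- and transcript-level markers); by
    default every planted marker uses ``config.effect_mode``.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"C{i + 1:03d}" for i in range(config.n_cohort)] \
        + [f"B{i + 1:03d}" for i in range(config.n_background)]
    n_samples = len(samples)
    cohort_idx = np.arange(config.n_cohort)

    sites = ["lung", "breast", "skin", "colon"]
    meta = pd.DataFrame({
        "sample_id": samples,
        "primary_site": [config.cohort_site] * config.n_cohort
        + [sites[i % len(sites)] for i in range(config.n_background)],
        "subtype": [f"{config.cohort_site}_clear_cell"] * config.n_cohort
        + [f"{sites[i % len(sites)]}_sub" for i in range(config.n_background)],
    })

    # gene / transcript universe
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    tpg = rng.integers(config.tpg_min, config.tpg_max + 1, size=config.n_genes)
    tr_ids, tr_parent = [], []
    for g, k in zip(genes, tpg):
        for t in range(k):
            tr_ids.append(f"{g}-T{t + 1:02d}")
            tr_parent.append(g)
    biotype = rng.choice(BIOTYPES, size=len(tr_ids), p=BIOTYPE_WEIGHTS)
    annotation = pd.DataFrame({"parent_gene": tr_parent, "biotype": biotype,
                               "level": TRANSCRIPT},
                              index=pd.Index(tr_ids, name="feature_id"))

    # KD targets are genes; planted-essential ones get distinct marker genes
    kd_genes = genes[:config.n_kd_genes]
    if config.n_kd_genes > config.n_genes:
        raise ValueError("n_kd_genes cannot exceed n_genes")
    n_planted = int(round(config.frac_essential * config.n_kd_genes))
    planted_kd = kd_genes[:n_planted]
    if _modes is None:
        modes = [config.effect_mode] * n_planted
    else:
        if len(_modes) != n_planted:
            raise ValueError("one mode per planted-essential KD target")
        modes = list(_modes)

    # sensitivity classes
    sensitive = np.zeros((config.n_kd_genes, n_samples), dtype=bool)
    bg = rng.random((config.n_kd_genes, n_samples)) \
        < config.background_sensitive_rate
    sensitive |= bg
    n_sens = int(round(config.frac_sensitive_in_cohort * config.n_cohort))
    for i, kd in enumerate(kd_genes):
        if kd in planted_kd:
            chosen = rng.choice(cohort_idx, size=n_sens, replace=False)
            sensitive[i, cohort_idx] = False
            sensitive[i, chosen] = True
    scores = _draw_scores(rng, sensitive)

    # knock out entries (keep >= 1 observed per row)
    if config.missing_frac > 0:
        holes = rng.random(scores.shape) < config.missing_frac
        keep_one = rng.integers(0, n_samples, size=scores.shape[0])
        holes[np.arange(scores.shape[0]), keep_one] = False
        scores = np.where(holes, np.nan, scores)

    # baseline log2 expression per transcript
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=len(tr_ids))
    base = pd.Series(baseline, index=tr_ids)

    # planted-essential KD genes stay expressed: floor their top transcript
    for kd in planted_kd:
        own = annotation.index[annotation["parent_gene"] == kd]
        if len(own) and base[own].max() < 3.0:
            base[own[int(np.argmax(base[own].to_numpy()))]] = 3.0

    # assign marker genes (never a KD target) and fix sibling dominance
    marker_pool = [g for g in genes if g not in kd_genes]
    if len(marker_pool) < n_planted and config.effect_mode != NULL:
        raise ValueError("not enough non-KD genes to host planted markers")
    truth_rows = []
    marker_plan = []   # (kd_index, mode, up transcript, sibling or None)
    pool_iter = iter(marker_pool)
    for kd, mode in zip(planted_kd, modes):
        if mode == NULL:
            continue
        mg = next(pool_iter)
        members = annotation.index[annotation["parent_gene"] == mg]
        if mode == TRANSCRIPT_LEVEL:
            while len(members) < 2:
                mg = next(pool_iter)
                members = annotation.index[annotation["parent_gene"] == mg]
            vals = base[members].to_numpy()
            up = members[int(np.argmin(vals))]
            sib = members[int(np.argmax(vals))]
            # up-isoform comfortably expressed (survives the median filter);
            # sibling dominant enough that compensation never exhausts its TPM
            base[up] = config.baseline_log2_mean + 1.0
            base[sib] = base[up] + config.effect_size + 3.0
            marker_plan.append((kd_genes.index(kd), mode, mg, up, sib))
            truth_rows.append((kd, mg, up, mode))
        else:
            # comparable-abundance isoforms: aggregating them averages noise,
            # so the gene-level row is the strongest marker of its own shift
            base[members] = config.baseline_log2_mean + 1.0
            marker_plan.append((kd_genes.index(kd), mode, mg, None, None))
            truth_rows.append((kd, mg, mg, mode))

    # per-sample expression and planted shifts
    log2x = base.to_numpy()[:, None] \
        + rng.normal(0.0, config.noise_sd, size=(len(tr_ids), n_samples))
    # the dominant sibling carries the parent gene's total; a tight noise
    # keeps that total class-balanced so the switch is invisible at gene level
    row_of = {t: i for i, t in enumerate(tr_ids)}
    for _, mode, _, _, sib in marker_plan:
        if mode == TRANSCRIPT_LEVEL:
            i = row_of[sib]
            log2x[i] = base[sib] + rng.normal(0.0, 0.03, size=n_samples)
    tpm = np.power(2.0, log2x)
    tpm_df = pd.DataFrame(tpm, index=pd.Index(tr_ids, name="feature_id"),
                          columns=samples)
    for kd_i, mode, mg, up, sib in marker_plan:
        mask = sensitive[kd_i]
        if mode == GENE_LEVEL:
            members = annotation.index[annotation["parent_gene"] == mg]
            tpm_df.loc[members, mask] *= 2.0 ** config.effect_size
        else:
            up_vals = tpm_df.loc[up, mask].to_numpy()
            delta = up_vals * (2.0 ** config.effect_size - 1.0)
            tpm_df.loc[up, mask] = up_vals + delta
            sib_vals = tpm_df.loc[sib, mask].to_numpy()
            tpm_df.loc[sib, mask] = np.maximum(sib_vals - delta, 1e-9)

    expr = ExpressionSet(tpm_df, annotation)
    ess = EssentialityMatrix(
        pd.DataFrame(scores, index=pd.Index(kd_genes, name="kd_gene"),
                     columns=samples))
    truth = SimTruth(
        markers=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
        essential_kd=list(planted_kd),
        sensitive=pd.DataFrame(sensitive, index=kd_genes, columns=samples))
    return expr, ess, meta, truth


def worked_fixture() -> tuple[ExpressionSet, EssentialityMatrix, pd.DataFrame,
                              SimTruth]:
    """Tiny deterministic dataset used throughout the documentation.

    8 genes (24-ish transcripts), 4 KD targets of which 2 are planted
    cohort-essential: one with a gene-level expression marker and one with
    a transcript-level marker whose sibling compensates the gene total.
    14 cohort + 30 background samples; no missing scores, so every number
    downstream is reproducible to the bit.
    """
    config = SimConfig(n_cohort=14, n_background=30, n_kd_genes=4, n_genes=8,
                       tpg_min=2, tpg_max=4, frac_essential=0.5,
                       frac_sensitive_in_cohort=0.5,
                       background_sensitive_rate=0.02, effect_size=4.0,
                       noise_sd=0.5, missing_frac=0.0, seed=20240401)
    return generate(config, _modes=[GENE_LEVEL, TRANSCRIPT_LEVEL])


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. parsed YAML)."""
    return SimConfig(**d)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
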