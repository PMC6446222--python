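# Methods

This note documents the statistical procedure implemented in `isomark`,
its tunable parameters, the synthetic-data generator used for testing, and
the numerical and design choices made where more than one defensible
option existed.

## Inputs and preprocessing

The engine consumes three tables over a shared set of cell-line samples:
transcript-level expression in TPM with a transcript→gene annotation, a
matrix of continuous essentiality scores (DEMETER-style: more negative =
the KD target is more essential for that line, −2 the conventional
essentiality cutoff) which may contain missing values, and per-sample
metadata (primary site, subtype) used for cohort selection. Both matrices
are oriented features/KD-genes in rows and samples in columns; samples are
matched by exact string id, and at least 4 shared samples are required
(two per group is the minimum for a pooled two-sample variance).

* **Imputation.** Missing essentiality scores are filled by k-nearest-
  neighbour averaging over KD-gene rows (k = 10 by default; Euclidean
  distance over mutually observed columns scaled by the fraction observed;
  a missing entry becomes the mean of its column over the k nearest rows).
  The heavy lifting is delegated to `sklearn.impute.KNNImputer`, whose
  nan-Euclidean neighbour averaging is exactly this rule; observed entries
  are restored verbatim afterwards so imputation can never perturb them.
  A row with no observed value is an error.
* **Dichotomization.** Sensitive iff score < thr with *strict* inequality;
  thr = −2 by default. A score of exactly −2 is resistant.
* **Gene aggregation.** Gene TPM = sum of member-transcript TPM (TPM is
  additive across a gene's transcripts). Gene-level rows carry the
  biotype tag `gene_aggregate` and feature_id equal to the gene id.
* **Log transform.** log2(TPM + offset), offset 1 by default so zeros map
  to zero. The offset is configurable; it must be positive.
* **Expression filter.** Two stages, applied separately within
  transcript-level and gene-level rows: (1) drop features with zero TPM in
  *every loaded sample* (cohort and background alike); (2) keep features
  whose mean TPM over the selected cohort is ≥ the q-quantile (default
  q = 0.5, linear-interpolation quantile, ties kept) of all stage-1
  survivors' cohort means. Whether the original tooling filtered
  gene-level rows by the same quantile rule as transcripts is not
  documented anywhere we know of; applying the rule per level keeps the
  two candidate pools comparably sized and is this package's choice.

## Essential-gene screen

Within a selected cohort (which must be a strict subset of the samples, so
a background exists), each KD gene is scored by

* `frac_sensitive_cohort` — fraction of cohort lines sensitive to the KD;
* `enrichment` — by default the *ratio* of cohort to background sensitive
  fractions (risk ratio). The specificity parameter is sometimes labelled
  an odds ratio in this field's tooling while being described operationally
  as "the percentage must be k times larger"; both definitions are exposed
  (`enrichment_definition="ratio"|"odds"`), ratio being the default since
  it matches the operational description. A zero background fraction with
  a positive cohort fraction yields +∞ (the criterion passes).
* `frac_expressed_when_sensitive` — fraction of the *cohort-sensitive*
  lines in which the KD gene's own aggregate expression exceeds the TPM
  threshold (strict >). A gene with zero sensitive cohort lines fails
  outright.

A gene passes when all three statistics meet their thresholds. Two presets
ship with the package: a case-study preset (min fraction sensitive 0.25,
enrichment ≥ 2, TPM > 1 in ≥ 75% of sensitive lines) and a permissive
overview preset (enrichment ≥ 1, otherwise identical — the overview use
case only pins down the enrichment and expression cutoffs, so the
remaining fields are carried over from the case-study preset). Output is
sorted by (frac_sensitive_cohort desc, enrichment desc, gene id asc); the
lexicographic tiebreak keeps runs deterministic.

## Moderated t-test

For one KD target, cohort lines split into sensitive/resistant (each group
needs ≥ 2 lines; targets that fail this are skipped with a logged reason
rather than aborting a genome-wide run). Per feature: logFC = mean(S) −
mean(R) of log2-expression, pooled variance s² with df = n_S + n_R − 2.

Hyperparameters (d₀, s₀²) are fitted by method of moments on the log
variances: with e = ln s² − ψ(df/2) + ln(df/2), `var(e) − ψ′(df/2)`
estimates ψ′(d₀/2) (solved by a Newton iteration on the trigamma inverse)
and mean(e) fixes s₀². When the observed spread does not exceed the
χ²-sampling spread, d₀ = ∞ and every posterior variance equals s₀².
Zero variances are excluded from the fit; an all-zero variance set is an
error. Genes and transcripts are pooled into a single squeeze per KD
target — they are tested together and split only afterwards for FDR
grouping. The prior is constant (no expression trend, no robust variant).

The moderated statistic t = logFC/√(s̃²(1/n_S + 1/n_R)) with s̃² =
(d₀s₀² + df·s²)/(d₀+df) is referred to Student-t with d₀ + df degrees of
freedom; d₀ = 0 reduces to the classical pooled t-test (used as an oracle
in the tests) and d₀ = ∞ to a z-test against s₀². The unit tests verify
exact agreement of the whole path (d₀, s₀², posterior variances,
p-values) with limma's `eBayes` on the same matrix. P-values are
two-sided throughout — a biomarker may go up or down. A feature with zero
posterior variance and nonzero logFC gets t = ±∞, p = 0, by convention
rather than as an error. Unequal residual df across features does not
arise because expression has no missingness by construction.

## Grouped local FDR

All (target, feature) tests are partitioned into 2n covariate groups by
(KD target, feature level). Per group with at least `min_group_size`
(default 100) tests:

* **π₀** by the Storey tail estimator π₀(λ) = #{p > λ}/(m(1−λ)) on
  λ ∈ {0.05, …, 0.95}, smoothed by a least-squares cubic in λ and
  evaluated at λ = 0.95, clamped into (1/m, 1]. The fit is weighted by
  (1−λ) — the sampling variance of π₀(λ) grows like 1/(1−λ), and the
  weights keep the high-λ grid points from dominating the endpoint. This
  cubic-in-λ smoother plays the role of the natural cubic smoothing
  spline used by the classical q-value pathway; at m around 2000 the
  estimator at λ = 0.95 carries an irreducible sd of roughly 0.05–0.1 on
  fully null data, which any λ→1 extrapolation inherits.
* **lfdr** on the probit scale: z = Φ⁻¹(p) with p clipped to
  [1e−15, 1−1e−15], f̂ a Gaussian KDE of z with Silverman-rule bandwidth
  (as implemented by `scipy.stats.gaussian_kde`), lfdr = π₀φ(z)/f̂(z),
  capped at 1 and forced non-decreasing in p by a running maximum over the
  p-sorted order. If all p in a group are identical the group's lfdr is
  min(π₀, 1).

Groups smaller than `min_group_size` use a conservative fallback — π₀ = 1
with the level-wide *pooled* density across all targets (kernel density on
fewer than ~100 points is unstable, and conservatism protects the
ranking); such groups are flagged `fallback_used`. If even the pooled
level has fewer than 2 tests, lfdr = 1. The per-group π₀ is reported so
gene- vs transcript-group informativeness can be compared per target: a
low transcript-group π₀ signals splicing-driven biomarkers.

## Marker selection, ranking, summaries

One record per (essential target, candidate parent gene): the gene-level
lfdr is compared with the minimum lfdr among the gene's filtered-in
transcripts; the smaller wins, and ties within 1e−12 resolve to the gene —
the parsimonious choice when both are equally supported. Candidates are
genome-wide (every filtered feature against every target); the target
itself may serve as its own marker, and no positional/locus exclusion is
applied. Records passing P < 1e−4, |log2FC| > 2, lfdr < 0.1 (all
configurable) are ranked by (lfdr asc, |logFC| desc, marker id asc).

The rank-based AUC of the selected marker (Mann–Whitney concordance with
midranks for ties) is reported twice: raw — P(sensitive line expresses
higher than resistant line) — and oriented by the sign of the marker's
logFC, so a marker perfectly consistent with its fold-change direction
scores 1 regardless of direction. Summaries per essential gene (fraction
of its passing markers that are transcripts) and per biotype (marker
biotype proportions next to the whole-annotation reference proportions)
come from the same record table; a gene with no passing markers is
excluded from the proportion summary rather than reported as 0.

## Synthetic data generator

`isomark.synthetic.generate(SimConfig)` emulates the structure the model
assumes, with defaults chosen as a realistic focused-cohort study:
14 cohort + 30 background lines, 20 KD targets drawn from the simulated
gene universe (so screened targets have gene-level expression rows),
transcript baselines log-normal (log2 mean 3, sd 1.5), within-feature
noise 0.5 log2 units, planted effect 4 log2 units, 2% missing scores,
half of the cohort sensitive to each planted-essential target and a 2%
background sensitivity rate. Scores come from two normals (means −4/0,
sd 1) clipped to ±0.2 away from the −2 threshold so dichotomization
reproduces the planted classes exactly; knocked-out entries are
re-estimated by imputation and can therefore (rarely) flip a class.

Planted markers live in genes never used as KD targets. A gene-level
effect shifts all of a marker gene's isoforms by the effect size in the
sensitive samples; the marker gene's isoforms are given equal baselines so
the aggregate's noise-averaging makes the gene row the strongest marker of
its own shift. A transcript-level effect raises one isoform and lowers a
dominant sibling by the same TPM amount per sample, leaving the gene total
exactly unchanged; the sibling is constructed dominant (baseline gap =
effect + 3 log2 units, so compensation cannot exhaust its TPM) and given a
tight noise (sd 0.03) so the gene total stays class-balanced to within a
few percent. Planted-essential targets get a floor on their top transcript
baseline so the expressed-when-essential criterion reflects the planting.
The truth table lists every planted (target, marker gene, marker feature,
mode); `worked_fixture()` is a fixed-seed instance (8 genes, 44 samples,
one gene-level and one transcript-level marker) used throughout the
documentation and tests.

What the generator does *not* emulate: correlated co-expression modules,
library-size/compositional artifacts, batch effects, heavy-tailed or
count-based noise, annotation errors, and dependence between targets'
sensitivity patterns. Passing tests on this generator demonstrate that the
machinery recovers the signal structure it models — not that real CCLE/
Achilles data meet those assumptions.

## Problem sizes used in the verification suite

The statistical acceptance tests run at deliberately desk-scale sizes
chosen as the smallest that make the assertions statistically meaningful:
5000 features for hyperparameter and π₀ recovery, ~2000 features × 20
targets × 10 seeds for the null false-call and planted-recovery pipelines
(the planted run uses effect 4, noise 0.5, 10 planted targets per seed).
Larger runs sharpen the estimates but do not change any conclusion.

## Known limitations

* The lfdr of a small (fallback) group borrows the level-wide density;
  lfdr values from fallback groups of different levels are then not
  estimated from the same density and near-ties between them are less
  meaningful — the tie-to-gene rule makes this conservative for isoform
  claims.
* Storey's π₀ at λ = 0.95 is noisy below ~m = 1000 tests per group; the
  group-size gate exists precisely to route such groups to the π₀ = 1
  fallback.
* The moderated test assumes homoscedastic normal log-expression within
  groups and a common residual df across features; count noise at very low
  TPM violates normality, which the |log2FC| > 2 threshold partly guards.
* Essentiality imputation precedes dichotomization, so heavily missing
  rows can change their sensitive/resistant split; rows missing more than
  ~half their entries deserve scrutiny upstream.
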