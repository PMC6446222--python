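"""Screen KD genes for cohort-specific essentiality.

A KD gene passes the screen when, within the selected cohort, (i) it is
essential (sensitive call) in at least a minimum fraction of samples,
(ii) its cohort sensitive fraction is enriched over the background cell
lines by at least a minimum factor, and (iii) the gene is expressed above a
TPM threshold in at least a minimum fraction of the cohort samples in which
it is essential.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import GENE, ExpressionSet, SensitivityMatrix

#: preset used for broad multi-subtype overviews (permissive specificity)
OVERVIEW_PRESET = {
    "demeter_thr": -2.0,
    "min_frac_sensitive": 0.25,
    "min_enrichment": 1.0,
    "expr_tpm_thr": 1.0,
    "min_frac_expressed": 0.75,
}

#: preset used for a focused single-cohort case study
CASE_STUDY_PRESET = {
    "demeter_thr": -2.0,
    "min_frac_sensitive": 0.25,
    "min_enrichment": 2.0,
    "expr_tpm_thr": 1.0,
    "min_frac_expressed": 0.75,
}

SCREEN_COLUMNS = ["kd_gene", "n_cohort", "frac_sensitive_cohort",
                  "frac_sensitive_rest", "enrichment",
                  "frac_expressed_when_sensitive", "passes"]


def defaults_overview() -> tuple[dict, dict]:
    """Return (overview preset, case-study preset) parameter dictionaries."""
    return dict(OVERVIEW_PRESET), dict(CASE_STUDY_PRESET)


def _enrichment(fc: float, fr: float, definition: str) -> float:
    if definition == "ratio":
        if fr > 0:
            return fc / fr
        return math.inf if fc > 0 else 0.0
    if definition == "odds":
        num = fc / (1.0 - fc) if fc < 1.0 else math.inf
        den = fr / (1.0 - fr) if fr < 1.0 else math.inf
        if den == 0:
            return math.inf if num > 0 else 0.0
        if math.isinf(num):
            return 0.0 if math.isinf(den) else math.inf
        if math.isinf(den):
            return 0.0
        return num / den
    raise ValueError(f"unknown enrichment definition {definition!r}")


def screen(sens: SensitivityMatrix, expr: ExpressionSet, cohort,
           min_frac_sensitive: float = CASE_STUDY_PRESET["min_frac_sensitive"],
           min_enrichment: float = CASE_STUDY_PRESET["min_enrichment"],
           expr_tpm_thr: float = CASE_STUDY_PRESET["expr_tpm_thr"],
           min_frac_expressed: float = CASE_STUDY_PRESET["min_frac_expressed"],
           enrichment_definition: str = "ratio") -> pd.DataFrame:
    """Screen every KD gene against the three cohort-essentiality criteria.

    ``expr`` must carry gene-level rows (see ``aggregate_gene_tpm``) so the
    expressed-when-essential criterion can read the KD gene's own TPM.
    Returns one row per KD gene, sorted by (frac_sensitive_cohort desc,
    enrichment desc, kd_gene asc).
    """
    all_samples = list(sens.calls.columns)
    cohort = [s for s in all_samples if s in set(cohort)]
    rest = [s for s in all_samples if s not in set(cohort)]
    if not cohort:
        raise ValueError("empty cohort")
    if not rest:
        raise ValueError("cohort equals all samples; no background left "
                         "for the enrichment criterion")

    gene_tpm = expr.tpm.loc[expr.annotation["level"] == GENE]
    records = []
    n_cohort = len(cohort)
    for kd in sens.calls.index:
        calls_cohort = sens.calls.loc[kd, cohort].to_numpy()
        calls_rest = sens.calls.loc[kd, rest].to_numpy()
        fc = float(calls_cohort.mean())
        fr = float(calls_rest.mean())
        enr = _enrichment(fc, fr, enrichment_definition)
        sens_samples = [s for s, c in zip(cohort, calls_cohort) if c]
        if sens_samples and kd in gene_tpm.index:
            expressed = (gene_tpm.loc[kd, sens_samples] > expr_tpm_thr)
            fe = float(np.mean(expressed.to_numpy()))
        else:
            fe = 0.0
        passes = (len(sens_samples) > 0
                  and fc >= min_frac_sensitive
                  and enr >= min_enrichment
                  and fe >= min_frac_expressed)
        records.append((kd, n_cohort, fc, fr, enr, fe, bool(passes)))

    out = pd.DataFrame(records, columns=SCREEN_COLUMNS)
    out = out.sort_values(
        ["frac_sensitive_cohort", "enrichment", "kd_gene"],
        ascending=[False, False, True], kind="mergesort").reset_index(drop=True)
    return out
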