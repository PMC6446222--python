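"""Local false discovery rates with covariate grouping.

All (KD target, feature) tests are partitioned into 2n groups — one per
(KD target, feature level in {gene, transcript}) — and each group gets its
own null proportion pi0 and local FDR curve:

    lfdr(z) = pi0 * f0(z) / f(z)

with z the probit transform of the p-value, f0 the standard normal density
(the image of uniform p-values) and f a Gaussian kernel density estimate of
the observed z.  pi0 uses the Storey tail estimator smoothed over a lambda
grid.  Comparing pi0 between a target's gene group and transcript group
indicates which feature level carries the biomarker signal.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GENE, TRANSCRIPT

#: p-value clipping bound before the probit transform (avoids infinite z)
P_CLIP = 1e-15

DEFAULT_MIN_GROUP_SIZE = 100

PI0_LAMBDAS = np.round(np.arange(0.05, 0.96, 0.05), 2)

GROUP_COLUMNS = ["kd_gene", "level", "m", "pi0", "fallback_used"]


def estimate_pi0(p, lambdas=PI0_LAMBDAS) -> float:
    """Storey pi0: tail counts over a lambda grid, cubic-smoothed at 0.95.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed on the
    grid, smoothed with a least-squares cubic in lambda, evaluated at the
    largest lambda and clamped into (1/m, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    lambdas = np.asarray(lambdas, dtype=float)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if lambdas.size >= 4:
        # var(pi0(lambda)) ~ 1/(1 - lambda): weight the fit accordingly
        coef = np.polyfit(lambdas, pi0_l, 3, w=np.sqrt(1.0 - lambdas))
        pi0 = float(np.polyval(coef, lambdas.max()))
    else:
        pi0 = float(pi0_l[-1])
    return float(min(max(pi0, 1.0 / m), 1.0))


def _probit(p: np.ndarray) -> np.ndarray:
    return stats.norm.ppf(np.clip(p, P_CLIP, 1.0 - P_CLIP))


def _monotonize(lfdr: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Enforce lfdr non-decreasing in p by a running maximum."""
    order = np.argsort(p, kind="mergesort")
    out = lfdr.copy()
    out[order] = np.maximum.accumulate(lfdr[order])
    return out


def estimate_lfdr(p, pi0: float, density: "stats.gaussian_kde | None" = None
                  ) -> np.ndarray:
    """Per-test local FDR = pi0 * phi(z) / f(z), capped at 1, monotone in p.

    ``density`` overrides the kernel density of z (used by the small-group
    fallback, which borrows a pooled density); by default it is estimated
    from these p-values with a Silverman-rule Gaussian kernel.
    """
    p = np.asarray(p, dtype=float)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    z = _probit(p)
    if density is None:
        if np.ptp(z) == 0 or p.size < 2:
            return np.full(p.size, min(pi0, 1.0))
        density = stats.gaussian_kde(z, bw_method="silverman")
    f = np.maximum(density(z), 1e-300)
    lfdr = np.minimum(pi0 * stats.norm.pdf(z) / f, 1.0)
    return _monotonize(lfdr, p)


def pooled_density(p) -> "stats.gaussian_kde | None":
    """Silverman-rule KDE of the probit-transformed p-values (None if degenerate)."""
    p = np.asarray(p, dtype=float)
    z = _probit(p)
    if p.size < 2 or np.ptp(z) == 0:
        return None
    return stats.gaussian_kde(z, bw_method="silverman")


def group_and_estimate(tests: pd.DataFrame,
                       min_group_size: int = DEFAULT_MIN_GROUP_SIZE
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(KD target, level) pi0 and lfdr for a table of test results.

    ``tests`` needs columns kd_gene, level and p.  Groups with at least
    ``min_group_size`` tests get their own Storey pi0 and kernel density;
    smaller groups fall back to pi0 = 1 with the level-wide pooled density
    (flagged ``fallback_used``).  Returns (tests with an ``lfdr`` column,
    group summary table).
    """
    required = {"kd_gene", "level", "p"}
    if not required.issubset(tests.columns):
        raise ValueError(f"tests table needs columns {sorted(required)}")
    out = tests.copy()
    lfdr_col = np.full(len(out), np.nan)
    level_arr = out["level"].to_numpy()
    p_arr = out["p"].to_numpy(dtype=float)
    pooled = {level: pooled_density(p_arr[level_arr == level])
              for level in (GENE, TRANSCRIPT)}
    groups = []
    # positional grouping: the feature_id index repeats across KD targets
    grouped = out.reset_index(drop=True).groupby(["kd_gene", "level"],
                                                 sort=True)
    for (kd, level), idx in grouped.indices.items():
        p = p_arr[idx]
        m = p.size
        if m >= min_group_size:
            pi0 = estimate_pi0(p)
            lfdr = estimate_lfdr(p, pi0)
            fallback = False
        else:
            pi0 = 1.0
            dens = pooled.get(level)
            if dens is None:
                lfdr = np.ones(m)
            else:
                lfdr = estimate_lfdr(p, pi0, density=dens)
            fallback = True
        lfdr_col[idx] = lfdr
        groups.append((kd, level, m, pi0, fallback))
    out["lfdr"] = lfdr_col
    groups_df = pd.DataFrame(groups, columns=GROUP_COLUMNS)
    return out, groups_df
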