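"""Empirical-Bayes moderated two-sample t-tests.

For one KD target, every candidate feature's log-expression is compared
between sensitive (S) and resistant (R) cell lines.  Per-feature pooled
variances s2 with common residual df are shrunk toward a prior variance
s0_2 with prior degrees of freedom d0, both estimated by the
method-of-moments fit of a scaled F distribution to the observed variances
(on the log scale, via digamma/trigamma moments).  The moderated statistic

    t = logfc / sqrt(s2_tilde * (1/nS + 1/nR)),
    s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)

is referred to a Student t with d0 + df degrees of freedom (standard normal
in the d0 -> infinity limit; the raw pooled t when d0 = 0).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import LogExpressionSet

STAT_COLUMNS = ["level", "mean_s", "mean_r", "logfc", "s2", "df_residual",
                "n_s", "n_r"]


def feature_stats(logexpr: LogExpressionSet, labels: pd.Series, features,
                  kd_gene: str = "?") -> pd.DataFrame:
    """Group means, log-fold-changes and pooled variances for one split.

    ``labels`` is a boolean Series over sample ids (True = sensitive).
    logfc = mean(S) - mean(R); s2 = (SS_S + SS_R) / (nS + nR - 2).
    """
    features = list(features)
    samples = list(labels.index)
    X = logexpr.logexpr.loc[features, samples].to_numpy()
    mask = labels.to_numpy(dtype=bool)
    n_s, n_r = int(mask.sum()), int((~mask).sum())
    if n_s < 2 or n_r < 2:
        raise ValueError(
            f"KD target {kd_gene!r}: need >= 2 samples per group "
            f"(sensitive={n_s}, resistant={n_r})")
    S, R = X[:, mask], X[:, ~mask]
    mean_s, mean_r = S.mean(axis=1), R.mean(axis=1)
    ss = ((S - mean_s[:, None]) ** 2).sum(axis=1) \
        + ((R - mean_r[:, None]) ** 2).sum(axis=1)
    df = n_s + n_r - 2
    out = pd.DataFrame(
        {"level": logexpr.annotation.loc[features, "level"].to_numpy(),
         "mean_s": mean_s, "mean_r": mean_r, "logfc": mean_s - mean_r,
         "s2": ss / df, "df_residual": df, "n_s": n_s, "n_r": n_r},
        index=pd.Index(features, name="feature_id"))
    return out


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def squeeze_variances(s2, df: int) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0_2 from pooled variances.

    Uses the log-variance moments: with e = ln(s2) - psi(df/2) + ln(df/2),
    var(e) - psi'(df/2) estimates psi'(d0/2) and mean(e) fixes s0_2.  When
    the observed spread is no larger than the chi-square sampling spread,
    d0 = +inf (all features share one variance s0_2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size == 0:
        raise ValueError("all pooled variances are zero; cannot fit prior")
    if s2.size < 2:
        return math.inf, float(s2.mean())
    half_df = df / 2.0
    e = np.log(s2) - special.digamma(half_df) + math.log(half_df)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    target = evar - float(special.polygamma(1, half_df))
    if target <= 1e-8:
        return math.inf, float(math.exp(emean))
    d0 = 2.0 * trigamma_inverse(target)
    s0_2 = math.exp(emean + float(special.digamma(d0 / 2.0))
                    - math.log(d0 / 2.0))
    return d0, s0_2


def moderated_t(stats_df: pd.DataFrame, d0: float, s0_2: float) -> pd.DataFrame:
    """Add posterior variances, moderated t statistics and two-sided p-values.

    d0 = 0 gives the classical pooled two-sample t-test; d0 = +inf gives a
    z-test against the common prior variance.  A feature with zero posterior
    variance gets t = +/-inf and p = 0 when its logfc is nonzero (t = 0,
    p = 1 when logfc is zero too).
    """
    out = stats_df.copy()
    df_res = out["df_residual"].to_numpy(dtype=float)
    s2 = out["s2"].to_numpy(dtype=float)
    if math.isinf(d0):
        s2t = np.full_like(s2, s0_2)
        df_total = np.full_like(s2, math.inf)
    else:
        s2t = (d0 * s0_2 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    se = np.sqrt(s2t * (1.0 / out["n_s"].to_numpy()
                        + 1.0 / out["n_r"].to_numpy()))
    logfc = out["logfc"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0),
                     np.sign(logfc) * math.inf)
    t = np.where((se == 0) & (logfc == 0), 0.0, t)
    p = np.empty_like(t)
    finite_df = np.isfinite(df_total)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(t == 0, 1.0, p)
    out["s2_tilde"] = s2t
    out["t"] = t
    out["p"] = np.clip(p, 0.0, 1.0)
    return out
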