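import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isomark.datatypes import TRANSCRIPT, LogExpressionSet
from isomark.modstats import (feature_stats, moderated_t, squeeze_variances,
                              trigamma_inverse)


def logexpr_from(matrix, samples):
    X = pd.DataFrame(matrix, columns=samples)
    X.index = [f"f{i}" for i in range(len(X))]
    ann = pd.DataFrame({"parent_gene": X.index, "biotype": "protein_coding",
                        "level": TRANSCRIPT}, index=X.index)
    return LogExpressionSet(X.astype(float), 1.0, ann)


def labels_for(samples, n_sensitive):
    return pd.Series([True] * n_sensitive
                     + [False] * (len(samples) - n_sensitive), index=samples)


class TestFeatureStats:
    def test_hand_pooled_variance(self):
        le = logexpr_from([[2.0, 4.0, 1.0, 3.0]], ["a", "b", "c", "d"])
        st = feature_stats(le, labels_for(["a", "b", "c", "d"], 2), ["f0"])
        row = st.iloc[0]
        assert row["logfc"] == pytest.approx(1.0)
        assert row["s2"] == pytest.approx(2.0)
        assert row["df_residual"] == 2

    def test_identical_groups_and_zero_variance(self):
        le = logexpr_from([[5.0, 5.0, 5.0, 5.0], [1.0, 3.0, 1.0, 3.0]],
                          ["a", "b", "c", "d"])
        st = feature_stats(le, labels_for(["a", "b", "c", "d"], 2),
                           ["f0", "f1"])
        assert st.loc["f0", "logfc"] == 0.0
        assert st.loc["f0", "s2"] == 0.0
        assert st.loc["f1", "logfc"] == 0.0

    def test_small_group_names_target(self):
        le = logexpr_from([[1.0, 2.0, 3.0]], ["a", "b", "c"])
        with pytest.raises(ValueError, match="MYC"):
            feature_stats(le, labels_for(["a", "b", "c"], 1), ["f0"],
                          kd_gene="MYC")


class TestSqueezeVariances:
    def test_equal_variances_give_infinite_prior_df(self):
        from scipy.special import digamma
        d0, s0 = squeeze_variances(np.full(50, 0.7), df=10)
        assert math.isinf(d0)
        # zero spread: s0_2 is the bias-corrected log-scale mean of s2
        expected = math.exp(math.log(0.7) - digamma(5.0) + math.log(5.0))
        assert s0 == pytest.approx(expected)
        mt = moderated_t(pd.DataFrame(
            {"logfc": [1.0], "s2": [0.7], "df_residual": [10],
             "n_s": [6], "n_r": [6]}), d0, s0)
        assert mt["s2_tilde"].iloc[0] == pytest.approx(s0)

    def test_prior_recovery_from_scaled_inv_chisq(self):
        rng = np.random.default_rng(7)
        d0_true, s0_true, df, m = 4.0, 1.0, 10, 5000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, m)
        s2 = sigma2 * rng.chisquare(df, m) / df
        d0, s0 = squeeze_variances(s2, df)
        assert abs(d0 - d0_true) < 1.0
        assert abs(s0 - s0_true) / s0_true < 0.10

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            squeeze_variances(np.zeros(20), df=4)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for x in (0.05, 0.8, 3.0, 40.0):
            assert trigamma_inverse(float(polygamma(1, x))) == \
                pytest.approx(x, rel=1e-6)


class TestModeratedT:
    def stats_frame(self, rng, m=200, ns=5, nr=6):
        X = rng.normal(size=(m, ns + nr))
        samples = [f"s{i}" for i in range(ns + nr)]
        le = logexpr_from(X, samples)
        return feature_stats(le, labels_for(samples, ns), list(le.logexpr.index))

    def test_hand_formula(self):
        mt = moderated_t(pd.DataFrame(
            {"logfc": [1.0], "s2": [2.0], "df_residual": [2],
             "n_s": [2], "n_r": [2]}), d0=0.0, s0_2=123.0)
        assert mt["t"].iloc[0] == pytest.approx(1.0 / math.sqrt(2.0))

    def test_zero_logfc_gives_p_one(self):
        mt = moderated_t(pd.DataFrame(
            {"logfc": [0.0], "s2": [1.0], "df_residual": [4],
             "n_s": [3], "n_r": [3]}), d0=2.0, s0_2=1.0)
        assert mt["t"].iloc[0] == 0.0
        assert mt["p"].iloc[0] == 1.0

    def test_d0_zero_matches_classical_pooled_t(self, rng):
        ns, nr = 5, 6
        X = rng.normal(size=(300, ns + nr))
        samples = [f"s{i}" for i in range(ns + nr)]
        le = logexpr_from(X, samples)
        st = feature_stats(le, labels_for(samples, ns), list(le.logexpr.index))
        mt = moderated_t(st, d0=0.0, s0_2=1.0)
        t_ref, p_ref = sps.ttest_ind(X[:, :ns], X[:, ns:], axis=1,
                                     equal_var=True)
        np.testing.assert_allclose(mt["t"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(mt["p"], p_ref, rtol=1e-12)

    def test_label_swap_negates_t_keeps_p(self, rng):
        st = self.stats_frame(rng)
        d0, s0 = squeeze_variances(st["s2"].to_numpy(), 9)
        mt = moderated_t(st, d0, s0)
        swapped = st.copy()
        swapped["logfc"] = -swapped["logfc"]
        swapped[["n_s", "n_r"]] = swapped[["n_r", "n_s"]].to_numpy()
        mt2 = moderated_t(swapped, d0, s0)
        np.testing.assert_allclose(mt2["t"], -mt["t"])
        np.testing.assert_allclose(mt2["p"], mt["p"])

    def test_shrinkage_bracketing(self, rng):
        st = self.stats_frame(rng, m=400)
        d0, s0 = squeeze_variances(st["s2"].to_numpy(), 9)
        mt = moderated_t(st, d0, s0)
        lo = np.minimum(st["s2"], s0) - 1e-12
        hi = np.maximum(st["s2"], s0) + 1e-12
        assert ((mt["s2_tilde"] >= lo) & (mt["s2_tilde"] <= hi)).all()

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        ns, nr = 6, 6
        X = rng.normal(size=(5000, ns + nr))
        samples = [f"s{i}" for i in range(ns + nr)]
        le = logexpr_from(X, samples)
        st = feature_stats(le, labels_for(samples, ns), list(le.logexpr.index))
        d0, s0 = squeeze_variances(st["s2"].to_numpy(), ns + nr - 2)
        mt = moderated_t(st, d0, s0)
        ks = sps.kstest(mt["p"], "uniform").statistic
        assert ks < 0.05

    def test_infinite_d0_closed_form_limit(self, rng):
        st = self.stats_frame(rng, m=50)
        s0 = 0.9
        mt = moderated_t(st, math.inf, s0)
        se = math.sqrt(s0 * (1 / st["n_s"].iloc[0] + 1 / st["n_r"].iloc[0]))
        np.testing.assert_allclose(mt["t"], st["logfc"] / se)


class TestAgainstLimma:
    """Independent cross-check of the variance squeeze and moderated test."""

    def test_matches_limma_ebayes(self, tmp_path, rng):
        ns = nr = 6
        m = 250
        sigma2 = 0.5 * 5 / rng.chisquare(5, m)
        X = rng.normal(0, np.sqrt(sigma2)[:, None], size=(m, ns + nr))
        X[:25, :ns] += 1.5
        mat = tmp_path / "mat.csv"
        out = tmp_path / "limma.csv"
        pd.DataFrame(X, index=[f"f{i}" for i in range(m)]).to_csv(mat)
        rcode = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv("{mat}", row.names=1))
            grp <- factor(c(rep("S",{ns}), rep("R",{nr})), levels=c("R","S"))
            fit <- eBayes(lmFit(x, model.matrix(~grp)))
            write.csv(data.frame(p=fit$p.value[,2], s2post=fit$s2.post,
                                 d0=fit$df.prior[1], s02=fit$s2.prior[1]),
                      "{out}")
        """)
        subprocess.run(["Rscript", "-e", rcode], check=True,
                       capture_output=True)
        ref = pd.read_csv(out, index_col=0)
        samples = [f"s{i}" for i in range(ns + nr)]
        le = logexpr_from(X, samples)
        st = feature_stats(le, labels_for(samples, ns), list(le.logexpr.index))
        d0, s0 = squeeze_variances(st["s2"].to_numpy(), ns + nr - 2)
        mt = moderated_t(st, d0, s0)
        assert d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert s0 == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(mt["p"], ref["p"], rtol=1e-6)
        np.testing.assert_allclose(mt["s2_tilde"], ref["s2post"], rtol=1e-6)
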