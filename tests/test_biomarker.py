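import numpy as np
import pandas as pd
import pytest

from isomark.biomarker import (auc, biotype_summary, rank_and_filter,
                               select_best, transcript_proportion,
                               transcript_proportion_summary)
from isomark.datatypes import GENE, TRANSCRIPT


def make_tests_table(rows):
    """rows: (feature_id, level, logfc, p, lfdr)."""
    df = pd.DataFrame(rows, columns=["feature_id", "level", "logfc", "p",
                                     "lfdr"]).set_index("feature_id")
    df["kd_gene"] = "KD1"
    return df


def annotation_for(parents):
    ids, pg, level = [], [], []
    for parent, n_tr in parents.items():
        ids.append(parent); pg.append(parent); level.append(GENE)
        for i in range(n_tr):
            ids.append(f"{parent}-T{i+1}"); pg.append(parent)
            level.append(TRANSCRIPT)
    return pd.DataFrame({"parent_gene": pg, "biotype": "protein_coding",
                         "level": level}, index=ids)


class TestSelectBest:
    ann = annotation_for({"G1": 2})

    def test_transcript_wins_when_smaller_lfdr(self):
        tk = make_tests_table([("G1", GENE, 0.5, 0.37, 0.7),
                          ("G1-T1", TRANSCRIPT, 3.2, 2.62e-7, 0.01),
                          ("G1-T2", TRANSCRIPT, -0.1, 0.8, 0.95)])
        rec = select_best(tk, self.ann, "G1", "KD1")
        assert rec["Group_bmkr"] == "Transcript"
        assert rec["Transcript_bmkr"] == "G1-T1"
        assert rec["Lfdr"] == pytest.approx(0.01)
        assert rec["tr"] == 2

    def test_gene_wins_when_transcripts_weak(self):
        tk = make_tests_table([("G1", GENE, 2.5, 1e-6, 0.01),
                          ("G1-T1", TRANSCRIPT, 1.0, 0.2, 0.5),
                          ("G1-T2", TRANSCRIPT, 1.0, 0.3, 0.6)])
        rec = select_best(tk, self.ann, "G1", "KD1")
        assert rec["Group_bmkr"] == "Gene"
        assert rec["Transcript_bmkr"] == ""

    def test_exact_tie_resolves_to_gene(self):
        tk = make_tests_table([("G1", GENE, 2.5, 1e-6, 0.05),
                          ("G1-T1", TRANSCRIPT, 3.0, 1e-7, 0.05)])
        assert select_best(tk, self.ann, "G1", "KD1")["Group_bmkr"] == "Gene"

    def test_absent_parent_returns_none(self):
        tk = make_tests_table([("G1", GENE, 1.0, 0.5, 0.9)])
        assert select_best(tk, self.ann, "G99", "KD1") is None


class TestRankAndFilter:
    def records(self, rows):
        return pd.DataFrame(rows, columns=["Gene_Ess", "Gene_bmkr",
                                           "Transcript_bmkr", "tr", "logFC",
                                           "Lfdr", "P", "Group_bmkr"])

    def test_threshold_semantics(self):
        recs = self.records([
            ("K", "G1", "", 1, 2.5, 0.05, 1e-5, "Gene"),    # kept
            ("K", "G2", "", 1, 1.5, 0.05, 1e-5, "Gene"),    # |logFC| too small
            ("K", "G3", "", 1, 3.0, 0.2, 1e-5, "Gene"),     # lfdr too large
            ("K", "G4", "", 1, 3.0, 0.05, 1e-3, "Gene")])   # p too large
        out = rank_and_filter(recs)
        assert out["Gene_bmkr"].tolist() == ["G1"]

    def test_sorted_by_lfdr_then_abs_logfc(self):
        recs = self.records([
            ("K", "G1", "", 1, 2.5, 0.02, 1e-5, "Gene"),
            ("K", "G2", "", 1, -4.0, 0.01, 1e-5, "Gene"),
            ("K", "G3", "", 1, 3.0, 0.01, 1e-5, "Gene")])
        out = rank_and_filter(recs)
        assert out["Gene_bmkr"].tolist() == ["G2", "G3", "G1"]

    def test_subset_and_tightening_shrinks(self):
        rng = np.random.default_rng(0)
        recs = self.records([
            ("K", f"G{i}", "", 1, float(rng.normal(0, 3)),
             float(rng.uniform(0, 0.3)), float(10 ** -rng.uniform(2, 8)),
             "Gene") for i in range(50)])
        base = rank_and_filter(recs, 1e-3, 1.0, 0.2)
        tighter = rank_and_filter(recs, 1e-4, 2.0, 0.1)
        assert set(tighter["Gene_bmkr"]) <= set(base["Gene_bmkr"])
        assert set(base["Gene_bmkr"]) <= set(recs["Gene_bmkr"])


class TestAuc:
    def test_perfect_separation(self):
        oriented, raw = auc([3, 4, 1, 2], [True, True, False, False], +1)
        assert oriented == 1.0 and raw == 1.0

    def test_all_ties_give_half(self):
        oriented, raw = auc([2, 2, 2, 2], [True, True, False, False], +1)
        assert oriented == 0.5 and raw == 0.5

    def test_hand_mann_whitney_concordance(self):
        # sensitive {1,3} vs resistant {2,4}: 1 concordant pair of 4
        oriented, raw = auc([1, 3, 2, 4], [True, True, False, False], +1)
        assert raw == pytest.approx(0.25)
        assert oriented == pytest.approx(0.25)

    def test_negative_logfc_orients(self):
        oriented, raw = auc([1, 2, 3, 4], [True, True, False, False], -1)
        assert raw == 0.0 and oriented == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        lab = rng.random(20) < 0.4
        lab[0], lab[1] = True, False
        a1 = auc(x, lab, +1)
        a2 = auc(np.exp(2 * x) + 5, lab, +1)
        assert a1 == a2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [True, True], +1)


class TestSummaries:
    def records(self, groups, gene="K1"):
        return pd.DataFrame({
            "Gene_Ess": gene,
            "Gene_bmkr": [f"G{i}" for i in range(len(groups))],
            "Transcript_bmkr": [f"G{i}-T1" if g == "Transcript" else ""
                                for i, g in enumerate(groups)],
            "Group_bmkr": groups})

    def test_nine_of_ten_is_ninety_percent(self):
        recs = self.records(["Transcript"] * 9 + ["Gene"])
        assert transcript_proportion(recs) == pytest.approx(0.9)

    def test_all_gene_and_all_transcript(self):
        assert transcript_proportion(self.records(["Gene"] * 4)) == 0.0
        assert transcript_proportion(self.records(["Transcript"] * 3)) == 1.0

    def test_empty_is_undefined(self):
        with pytest.raises(ValueError):
            transcript_proportion(self.records([]))

    def test_summary_excludes_genes_without_passing_records(self):
        recs = pd.concat([self.records(["Transcript", "Gene"], gene="K1"),
                          self.records(["Transcript"], gene="K2")])
        out = transcript_proportion_summary(recs)
        assert out.set_index("Gene_Ess")["transcript_proportion"].to_dict() \
            == {"K1": 0.5, "K2": 1.0}

    def test_biotype_proportions(self):
        ann = pd.DataFrame(
            {"parent_gene": ["G0", "G1", "G2", "G3"],
             "biotype": ["protein_coding", "protein_coding", "lincRNA",
                         "retained_intron"],
             "level": [TRANSCRIPT] * 4},
            index=["G0-T1", "G1-T1", "G2-T1", "G3-T1"])
        recs = self.records(["Transcript", "Transcript", "Transcript",
                             "Gene"])
        markers, general = biotype_summary(recs, ann)
        assert markers == {"protein_coding": pytest.approx(2 / 3),
                           "lincRNA": pytest.approx(1 / 3)}
        assert sum(markers.values()) == pytest.approx(1.0)
        assert sum(general.values()) == pytest.approx(1.0)

    def test_no_transcript_markers_empty_map(self):
        ann = annotation_for({"G0": 1})
        markers, general = biotype_summary(self.records(["Gene"]), ann)
        assert markers == {}
        assert general
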