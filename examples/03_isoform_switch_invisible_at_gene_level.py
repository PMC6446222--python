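"""The isoform-switch phenomenon: a marker invisible in gene totals.

The demonstration dataset plants a transcript-level effect with a
compensating sibling: in sensitive lines one isoform rises ~16-fold while
a dominant sibling falls by the same TPM amount, so the parent gene's
total expression barely moves.  The gene-level test is null while the
isoform is a near-perfect biomarker — the reason to test transcripts at
all.
"""

import numpy as np

import isomark as im

expr, ess, meta, truth = im.worked_fixture()
cohort = im.select_cohort(meta, sites={"kidney"})
screen = im.find_essential_genes(expr, ess, cohort)

marker = truth.markers.set_index("mode").loc["transcript_level"]
pred = im.predict_biomarkers(expr, screen.sens, cohort, [marker.kd_gene])

tk = pred.tests[pred.tests["kd_gene"] == marker.kd_gene]
gene_row = tk[(tk.index == marker.marker_gene) & (tk["level"] == "gene")].iloc[0]
tr_row = tk[tk.index == marker.marker_feature].iloc[0]

labels = screen.sens.labels(marker.kd_gene, cohort)
agg = im.aggregate_gene_tpm(expr)
totals = agg.tpm.loc[marker.marker_gene, cohort]
rel = abs(totals[labels.to_numpy()].mean() - totals[(~labels).to_numpy()].mean()) \
    / totals[(~labels).to_numpy()].mean()

print(f"KD target {marker.kd_gene}, marker gene {marker.marker_gene}:")
print(f"  gene total TPM, sensitive vs resistant: "
      f"{totals[labels.to_numpy()].mean():.0f} vs "
      f"{totals[(~labels).to_numpy()].mean():.0f}  ({100*rel:.1f}% apart)")
print(f"  gene-level test:       logFC {gene_row['logfc']:+.2f}   "
      f"p {gene_row['p']:.2g}   lfdr {gene_row['lfdr']:.2g}")
print(f"  isoform {marker.marker_feature}:  logFC {tr_row['logfc']:+.2f}   "
      f"p {tr_row['p']:.2g}   lfdr {tr_row['lfdr']:.2g}")

rec = pred.ranking.set_index("Gene_bmkr").loc[marker.marker_gene]
print(f"  selected marker: {rec['Transcript_bmkr']} "
      f"(Group_bmkr = {rec['Group_bmkr']}, AUC = {rec['AUC']:.2f})")
print()
print("The isoform shifts ~4 log2 units between classes while the gene "
      "total moves\nonly a few percent: aggregating to gene level erases "
      "the signal entirely.")
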