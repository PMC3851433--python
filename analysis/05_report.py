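"""Assemble the consolidated run report and quality-control views.

Gathers the filter counts, per-pairing significant counts, Venn regions,
concordance table, mode percentages and functional-category rollups into one
report, alongside sample clustering and PCA coordinates.  Expect samples to
cluster by genotype and the report numbers to match the stage outputs
exactly.
"""

import pandas as pd

from common import RESULTS, RUN_DIR, STUDY_CONFIG
from troutarray import differential, pipeline, reporting
from troutarray.design import GroupDesign
from troutarray.preprocess import ExpressionMatrix, FilterReport

design = GroupDesign.read_sample_sheet(RUN_DIR / "samples.tsv")
matrix = ExpressionMatrix.read(RUN_DIR / "matrix.tsv", design)

# re-read the stage outputs this report consolidates
filter_lines = dict(
    line.split("\t") for line in
    (RESULTS / "02_filter_report.txt").read_text().strip().split("\n"))
filter_report = FilterReport(
    n_total=int(filter_lines["n_total"]),
    n_present=int(filter_lines["n_present"]),
    intensity_cutoff=float(filter_lines["intensity_cutoff"]),
    presence_rule=filter_lines["presence_rule"],
)
de_summary = pd.read_csv(RESULTS / "03_de_summary.tsv", sep="\t")
concordance_frame = pd.read_csv(RESULTS / "04_concordance.tsv", sep="\t")
percentages = pd.read_csv(RESULTS / "04_group_a_percentages.tsv",
                          sep="\t").iloc[0].to_dict()

lists = {}
for pairing in ("D_vs_Wa", "D_vs_Ws", "WD_vs_Wa", "WD_vs_Ws", "WD_vs_D"):
    members = pd.read_csv(RUN_DIR / "de" / f"{pairing}.tsv", sep="\t")
    lists[pairing] = differential.EntityList(
        pairing=tuple(pairing.split("_vs_")), alpha=0.05, fc_threshold=2.0,
        members=members)
venn_d = differential.venn_counts({k: lists[k] for k in ("D_vs_Wa", "D_vs_Ws")})
venn_wd = differential.venn_counts(
    {k: lists[k] for k in ("WD_vs_Wa", "WD_vs_Ws", "WD_vs_D")})

cmap = pipeline.synthetic_category_map(sorted(set(matrix.gene_names)),
                                       STUDY_CONFIG.seed)
category_tables = {name: reporting.categorize_updown(el, cmap)
                   for name, el in lists.items()}

cluster = reporting.hierarchical_cluster(matrix, axis="samples")
pd.DataFrame({"order": range(len(cluster.leaf_order)),
              "sample_id": cluster.ordered_labels,
              "group": [design.group_of[s] for s in cluster.ordered_labels]}
             ).to_csv(RESULTS / "05_cluster_samples.tsv", sep="\t", index=False)
pca = reporting.pca_coordinates(matrix, n_components=3)
coords = pca.coordinates.copy()
coords["group"] = [design.group_of[s] for s in coords.index]
coords.index.name = "sample_id"
coords.to_csv(RESULTS / "05_pca.tsv", sep="\t", float_format="%.4f")
print("sample leaf order:", " ".join(cluster.ordered_labels))
print("PCA variance explained:",
      " ".join(f"{v:.3f}" for v in pca.variance_explained))

report_path = reporting.render_report(
    RESULTS,
    filter_report=filter_report,
    de_summary=de_summary,
    venn_d=venn_d,
    venn_wd=venn_wd,
    concordance_frame=concordance_frame,
    percentages=percentages,
    category_tables=category_tables,
)
print(f"report written to {report_path}")
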