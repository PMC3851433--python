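"""Differential expression across all six group pairings.

Runs the omnibus ANOVA + BH + Tukey composition on the filtered matrix,
builds significant-entity lists at both significance levels with and without
the 2-fold filter, collapses replicate probes, and partitions the two
D-vs-wild lists by Venn.  Expect the D-vs-wild pairings to dominate the
counts and the stricter alpha to roughly halve each list.
"""

import pandas as pd

from common import RESULTS, RUN_DIR
from troutarray import differential
from troutarray.design import GroupDesign
from troutarray.preprocess import ExpressionMatrix

design = GroupDesign.read_sample_sheet(RUN_DIR / "samples.tsv")
matrix = ExpressionMatrix.read(RUN_DIR / "matrix.tsv", design)

de = differential.significant_entities(matrix, alpha=0.05, fc_threshold=2.0)
(RUN_DIR / "de").mkdir(exist_ok=True)
rows = []
for alpha in (0.05, 0.01):
    for fc in (2.0, 1.0):
        for pr, el in differential.derive_lists(de, alpha, fc).items():
            collapsed = differential.collapse_replicates(el)
            if alpha == 0.05 and fc == 2.0:
                collapsed.write(RUN_DIR / "de" / f"{pr[0]}_vs_{pr[1]}.tsv")
            rows.append({"pairing": f"{pr[0]}_vs_{pr[1]}", "alpha": alpha,
                         "fc_threshold": fc, "n": len(collapsed),
                         "n_up": collapsed.n_up, "n_down": collapsed.n_down})
summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "03_de_summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False))

wa = set(pd.read_csv(RUN_DIR / "de" / "D_vs_Wa.tsv", sep="\t")["entity_id"])
ws = set(pd.read_csv(RUN_DIR / "de" / "D_vs_Ws.tsv", sep="\t")["entity_id"])
counts = differential.venn_counts({"D_vs_Wa": wa, "D_vs_Ws": ws})
venn = pd.DataFrame([{"region": "&".join(k), "n": v}
                     for k, v in sorted(counts.items())])
venn.to_csv(RESULTS / "03_venn_d_vs_wild.tsv", sep="\t", index=False)
print("\nD-vs-wild Venn:")
print(venn.to_string(index=False))
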