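"""Classify inheritance modes on the combined D-vs-wild significant list.

Re-runs the ANOVA/Tukey machinery on the combined list, classifies each
entity under both wild references (Wa and Ws), partitions entities into
shared (A) and reference-unique (B, C) groups, and tabulates mode counts and
cross-reference concordance.  Expect group A to carry the bulk of the
entities with high concordance, and the concordant mode mix to reflect the
simulator's additive/dominant/recessive weights.
"""

import pandas as pd

from common import RESULTS, RUN_DIR
from troutarray import inheritance
from troutarray.design import GroupDesign
from troutarray.preprocess import ExpressionMatrix

design = GroupDesign.read_sample_sheet(RUN_DIR / "samples.tsv")
matrix = ExpressionMatrix.read(RUN_DIR / "matrix.tsv", design)
wa = set(pd.read_csv(RUN_DIR / "de" / "D_vs_Wa.tsv", sep="\t")["entity_id"])
ws = set(pd.read_csv(RUN_DIR / "de" / "D_vs_Ws.tsv", sep="\t")["entity_id"])

partition = inheritance.partition_groups(wa, ws)
combined = sorted(wa | ws)
calls_wa = inheritance.classify_modes(matrix, combined, "Wa")
calls_ws = inheritance.classify_modes(matrix, combined, "Ws")
for ref, calls in (("Wa", calls_wa), ("Ws", calls_ws)):
    inheritance.calls_frame(calls).to_csv(RUN_DIR / f"calls_{ref}.tsv",
                                          sep="\t", index=False,
                                          float_format="%.6g")

table = inheritance.concordance(calls_wa, calls_ws, partition)
frame = table.to_frame()
frame.to_csv(RESULTS / "04_concordance.tsv", sep="\t", index=False)
print(f"combined list: {len(combined)} entities "
      f"(A={len(partition['A'])}, B={len(partition['B'])}, "
      f"C={len(partition['C'])})")
print(frame.to_string(index=False))

pct = inheritance.summarize_percentages(table.concordant["A"])
pd.DataFrame([pct]).to_csv(RESULTS / "04_group_a_percentages.tsv", sep="\t",
                           index=False)
print("group A concordant percentages:",
      ", ".join(f"{k}={v}%" for k, v in pct.items()))
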