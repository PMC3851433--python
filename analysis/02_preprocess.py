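"""Normalize and filter the raw scans into the expression matrix.

Thresholds channels at 1.0, forms log2 ratios, removes the intensity-
dependent dye bias by LOWESS, centers each probe on its median and applies
the presence filter (raw signal >= 300 in every fish of at least one group,
good flag in >= 75% of samples).  Expect a present-call rate near the
expressed fraction of the simulation (~25%), echoing how sparsely a 44K
array is occupied by liver transcripts.
"""

from common import RESULTS, RUN_DIR
from troutarray.design import GroupDesign
from troutarray.preprocess import preprocess_scans, read_scan

design = GroupDesign.read_sample_sheet(RUN_DIR / "samples.tsv")
scans = [read_scan(RUN_DIR / "scans" / f"{s}.tsv", sample_id=s,
                   group=design.group_of[s])
         for s in design.samples]
matrix, report = preprocess_scans(scans, design)
matrix.write(RUN_DIR / "matrix.tsv")
report.write(RESULTS / "02_filter_report.txt")
print(f"present: {report.n_present}/{report.n_total} spots "
      f"({100 * report.n_present / report.n_total:.1f}%)")
print(f"rule: {report.presence_rule}")
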