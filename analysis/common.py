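"""Shared locations and the study-emulating configuration for the analysis runs.

The synthetic experiment mirrors the study geometry — four genotype groups
(Wa, Ws, D, WD) with six fish each against a pooled Ws reference, a minority
of spots expressed above the detection cutoff, replicate probes, dye bias and
flagged spots — on an array scaled to 6,000 spots so the whole analysis runs
in minutes.  Large intermediates (scan tables, matrices) live under scratch/,
small result tables under results/analysis/.
"""

from pathlib import Path

from troutarray.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results" / "analysis"

STUDY_CONFIG = SimulationConfig(
    n_genes=6000,
    n_per_group=6,
    expressed_fraction=0.25,
    fraction_affected=0.10,
    stage_effect_fraction=0.02,
    effect_size_log2=2.0,
    biological_cv=0.1,
    dye_bias_amplitude=0.5,
    background_mean=50.0,
    flagged_fraction=0.05,
    replicate_probe_fraction=0.1,
    seed=7,
)
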