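"""Simulation-backed performance measurements of the pipeline.

These routines quantify, on synthetic experiments with known ground truth,
how well the analysis machinery does its job: inheritance-mode recovery,
false-discovery-rate control on pure-null data, and dye-bias removal.  They
are used by the validation suite and the reproduction script; each takes a
seed and returns plain numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from troutarray import differential, inheritance, preprocess, simulate
from troutarray.design import GroupDesign


def mode_recovery(seed: int, n_per_mode: int = 200,
                  n_background: int = 7200) -> dict[str, float]:
    """Classification accuracy on genes with prescribed inheritance modes.

    Simulates ``n_per_mode`` genes each of additive, D-dominant, D-recessive
    and no-effect truth (parental effect 2 log2 units, biological CV 0.1,
    6 fish per group, all genes expressed), embedded in ``n_background``
    further unaffected genes.  The background matters: intensity-dependent
    normalization assumes most spots are unchanged, and a regulated gene
    shifts its own mean intensity A, so an array consisting mostly of
    regulated genes would feed real biology into the LOWESS fit.  Runs full
    preprocessing and classification (Wa reference) on the genes of interest
    and scores per-mode recovery.  Additive truth counts as recovered for
    either the additive or the resembling-additive label; a gene lost to
    filtering counts as missed.
    """
    modes = (["additive"] * n_per_mode + ["D-dominant"] * n_per_mode
             + ["D-recessive"] * n_per_mode + ["no-effect"] * n_per_mode)
    interest = set(range(len(modes)))
    config = simulate.SimulationConfig(
        n_genes=len(modes) + n_background, n_per_group=6, effect_size_log2=2.0,
        biological_cv=0.1, expressed_fraction=1.0,
        replicate_probe_fraction=0.0, seed=seed,
    )
    truth = simulate.truth_from_modes(modes + ["no-effect"] * n_background,
                                      config)
    interest_genes = {truth[i].gene_id for i in interest}
    scans = simulate.simulate_scans(truth, config)
    design = GroupDesign.balanced(config.n_per_group)
    matrix, _ = preprocess.preprocess_scans(scans, design)

    # classification operates on the combined D-vs-wild significant list, as
    # in the study; a gene never entering that list carries no genotype call
    de = differential.significant_entities(matrix, alpha=0.05, fc_threshold=2.0)
    combined = sorted(de.lists[("D", "Wa")].ids | de.lists[("D", "Ws")].ids)
    calls = inheritance.classify_modes(matrix, combined, "Wa", alpha=0.05)
    label_of = {matrix.gene_names[e]: c.label for e, c in calls.items()}
    truth = truth[:len(modes)]

    accepted = {
        "additive": ("additive", "resembling-additive"),
        "D-dominant": ("D-dominant",),
        "D-recessive": ("D-recessive",),
    }
    out: dict[str, float] = {}
    for mode, ok in accepted.items():
        genes = [t.gene_id for t in truth if t.mode == mode]
        hits = sum(label_of.get(g) in ok for g in genes)
        out[f"recovery_{mode}"] = hits / len(genes)
    null_genes = [t.gene_id for t in truth if t.mode == "no-effect"]
    false_pos = sum(label_of.get(g, "no-effect") != "no-effect"
                    for g in null_genes)
    out["no_effect_false_positive_rate"] = false_pos / len(null_genes)
    out["n_per_mode"] = float(n_per_mode)
    return out


def null_fdr(seed: int, n_genes: int = 2000, n_reps: int = 200,
             alpha: float = 0.05) -> dict[str, float]:
    """Empirical false discovery proportion at q <= alpha on pure-null data.

    Each replicate draws a ``n_genes`` x 24-fish matrix of exchangeable
    normal noise (no group effects) and runs the omnibus-ANOVA + BH stage;
    every entity passing q <= alpha is a false discovery.  Returns the mean
    false discovery proportion over replicates and its Monte-Carlo standard
    error.
    """
    design = GroupDesign.balanced(6)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    fdp = np.empty(n_reps)
    for r in range(n_reps):
        data = pd.DataFrame(
            rng.normal(size=(n_genes, len(design.samples))),
            index=[f"g{i}" for i in range(n_genes)], columns=design.samples,
        )
        matrix = preprocess.ExpressionMatrix(
            data=data,
            gene_names=pd.Series(data.index, index=data.index),
            design=design,
        )
        de = differential.significant_entities(matrix, alpha=alpha,
                                               fc_threshold=1.0)
        n_disc = int((de.table["q"] <= alpha).sum())
        fdp[r] = n_disc / max(n_disc, 1) if n_disc else 0.0
    return {
        "empirical_fdr": float(fdp.mean()),
        "mc_se": float(fdp.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": float(n_reps),
        "n_genes": float(n_genes),
    }


def dye_bias_attenuation(seed: int, n_spots: int = 10_000,
                         amplitude: float = 0.5) -> dict[str, float]:
    """Fold attenuation of the M-vs-A correlation by LOWESS normalization.

    Simulates one array of ``n_spots`` spots with a monotone low-intensity
    dye distortion of the given log2 amplitude and no real group effects,
    then compares |corr(M, A)| before and after normalization.
    """
    config = simulate.SimulationConfig(
        n_genes=n_spots, n_per_group=1, fraction_affected=0.0,
        stage_effect_fraction=0.0, replicate_probe_fraction=0.0,
        dye_bias_amplitude=amplitude, expressed_fraction=0.5,
        flagged_fraction=0.0, seed=seed,
    )
    scans = simulate.simulate_scans(simulate.simulate_truth(config), config)
    before = preprocess.threshold_and_log(scans[0])
    after = preprocess.lowess_normalize(before)
    r0 = float(np.corrcoef(before.table["M"], before.table["A"])[0, 1])
    r1 = float(np.corrcoef(after.table["M"], after.table["A"])[0, 1])
    return {
        "corr_before": r0,
        "corr_after": r1,
        "attenuation_fold": abs(r0) / max(abs(r1), 1e-12),
        "n_spots": float(n_spots),
    }
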