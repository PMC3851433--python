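"""End-to-end orchestration: simulate -> preprocess -> DE -> inheritance -> report.

Every stage writes its tab-delimited outputs under the run directory so a run
is fully auditable; identical configuration and seed give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from troutarray import differential, inheritance, preprocess, reporting, simulate
from troutarray.design import GroupDesign


def synthetic_category_map(gene_names: list[str], seed: int,
                           unknown_fraction: float = 0.2) -> reporting.CategoryMap:
    """Synthetic stand-in for a functional-annotation database.

    Assigns each gene a random umbrella term (a fraction stays unannotated),
    mimicking the partial coverage of real annotation lookups.  Purely a
    placeholder for a user-supplied gene -> category map.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    terms = reporting.DEFAULT_UMBRELLA_TERMS
    mapping = {}
    for name in gene_names:
        if rng.uniform() >= unknown_fraction:
            mapping[name] = terms[int(rng.integers(len(terms)))]
    return reporting.CategoryMap(mapping=mapping)


@dataclass
class RunResult:
    """In-memory handles to every stage output of one pipeline run."""

    config: simulate.SimulationConfig
    truth: list[simulate.TruthRecord]
    design: GroupDesign
    matrix: preprocess.ExpressionMatrix
    filter_report: preprocess.FilterReport
    de: differential.DEResult
    lists: dict[tuple[float, float], dict[tuple[str, str], differential.EntityList]]
    combined_entities: list[str]
    calls_wa: dict[str, inheritance.InheritanceCall]
    calls_ws: dict[str, inheritance.InheritanceCall]
    partition: dict[str, set]
    concordance: inheritance.ConcordanceTable
    percentages: dict[str, float]
    report_path: Path


def run_all(
    config: simulate.SimulationConfig,
    out_dir: str | Path,
    cutoff: float = preprocess.DEFAULT_CUTOFF,
    span: float = preprocess.DEFAULT_SPAN,
    alpha: float = 0.05,
    strict_alpha: float = 0.01,
    fc_threshold: float = 2.0,
    category_map: reporting.CategoryMap | None = None,
) -> RunResult:
    """Run the full pipeline on a fresh synthetic experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    truth = simulate.simulate_truth(config)
    scans = simulate.simulate_scans(truth, config)
    simulate.write_truth(truth, out / "truth.tsv")
    simulate.write_scans(scans, out / "scans")
    design = GroupDesign.balanced(config.n_per_group, config.groups)
    design.write_sample_sheet(out / "samples.tsv")

    # --- preprocess -------------------------------------------------------
    matrix, filter_report = preprocess.preprocess_scans(
        scans, design, cutoff=cutoff, span=span
    )
    matrix.write(out / "matrix.tsv")
    filter_report.write(out / "filter_report.txt")

    # --- differential expression -----------------------------------------
    de = differential.significant_entities(matrix, alpha=alpha,
                                           fc_threshold=fc_threshold)
    combos = [(alpha, fc_threshold), (alpha, 1.0),
              (strict_alpha, fc_threshold), (strict_alpha, 1.0)]
    lists = {}
    for a, f in combos:
        raw = differential.derive_lists(de, alpha=a, fc_threshold=f)
        lists[(a, f)] = {pr: differential.collapse_replicates(el)
                         for pr, el in raw.items()}
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    summary_rows = []
    for (a, f), by_pair in lists.items():
        for pr, el in by_pair.items():
            name = f"{pr[0]}_vs_{pr[1]}_a{a:g}_fc{f:g}"
            el.write(de_dir / f"{name}.tsv")
            summary_rows.append(
                {"pairing": f"{pr[0]}_vs_{pr[1]}", "alpha": a, "fc_threshold": f,
                 "n": len(el), "n_up": el.n_up, "n_down": el.n_down}
            )
    de_summary = pd.DataFrame(summary_rows).sort_values(
        ["alpha", "fc_threshold", "pairing"]).reset_index(drop=True)

    headline = lists[(alpha, fc_threshold)]
    venn_d = differential.venn_counts(
        {"D_vs_Wa": headline[("D", "Wa")], "D_vs_Ws": headline[("D", "Ws")]}
    )
    venn_wd = differential.venn_counts(
        {
            "WD_vs_Wa": headline[("WD", "Wa")],
            "WD_vs_Ws": headline[("WD", "Ws")],
            "WD_vs_D": headline[("WD", "D")],
        }
    )

    # --- inheritance ------------------------------------------------------
    partition = inheritance.partition_groups(headline[("D", "Wa")],
                                             headline[("D", "Ws")])
    combined = sorted(set.union(*partition.values()))
    calls_wa = inheritance.classify_modes(matrix, combined, "Wa", alpha=alpha)
    calls_ws = inheritance.classify_modes(matrix, combined, "Ws", alpha=alpha)
    inherit_dir = out / "inheritance"
    inherit_dir.mkdir(exist_ok=True)
    for ref, calls in (("Wa", calls_wa), ("Ws", calls_ws)):
        inheritance.calls_frame(calls).to_csv(
            inherit_dir / f"calls_{ref}.tsv", sep="\t", index=False,
            float_format="%.6g")
    table = inheritance.concordance(calls_wa, calls_ws, partition)
    if sum(table.concordant["A"].values()) > 0:
        percentages = inheritance.summarize_percentages(table.concordant["A"])
    else:
        percentages = {b: 0.0 for b in inheritance.SHORT_BINS}

    # --- reporting --------------------------------------------------------
    cmap = category_map
    if cmap is None:
        cmap = synthetic_category_map([t.gene_id for t in truth], config.seed)
        cmap.write(out / "category_map.tsv")
    category_tables = {
        f"{pr[0]}_vs_{pr[1]}": reporting.categorize_updown(el, cmap)
        for pr, el in headline.items()
    }
    cluster = reporting.hierarchical_cluster(matrix, axis="samples")
    pd.DataFrame({"order": range(len(cluster.leaf_order)),
                  "sample_id": cluster.ordered_labels}).to_csv(
        out / "cluster_samples.tsv", sep="\t", index=False)
    pca = reporting.pca_coordinates(matrix, n_components=3)
    pca_out = pca.coordinates.copy()
    pca_out["group"] = [design.group_of[s] for s in pca_out.index]
    pca_out.index.name = "sample_id"
    pca_out.to_csv(out / "pca.tsv", sep="\t", float_format="%.6f")

    report_path = reporting.render_report(
        out,
        filter_report=filter_report,
        de_summary=de_summary,
        venn_d=venn_d,
        venn_wd=venn_wd,
        concordance_frame=table.to_frame(),
        percentages=percentages,
        category_tables=category_tables,
    )
    return RunResult(
        config=config, truth=truth, design=design, matrix=matrix,
        filter_report=filter_report, de=de, lists=lists,
        combined_entities=combined, calls_wa=calls_wa, calls_ws=calls_ws,
        partition=partition, concordance=table, percentages=percentages,
        report_path=report_path,
    )
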