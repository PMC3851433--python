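"""Descriptive artifacts: clustering, PCA, functional rollups, run report."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from troutarray.differential import EntityList
from troutarray.preprocess import ExpressionMatrix, FilterReport

#: umbrella terms for functional rollups; the named liver pathways plus
#: generic physiological categories (16 total)
DEFAULT_UMBRELLA_TERMS = (
    "response to stimulus",
    "cell/tissue structure and development",
    "transport",
    "lipid metabolism",
    "carbohydrate metabolism",
    "protein metabolism",
    "oxidation-reduction",
    "immune response",
    "growth",
    "signal transduction",
    "transcription",
    "translation",
    "cell cycle",
    "apoptosis",
    "ion homeostasis",
    "other",
)

UNKNOWN_CATEGORY = "unknown"


@dataclass
class CategoryMap:
    """gene_name -> functional umbrella term; unmapped genes are 'unknown'."""

    mapping: dict[str, str] = field(default_factory=dict)

    def category_of(self, gene_name: str) -> str:
        return self.mapping.get(gene_name, UNKNOWN_CATEGORY)

    @classmethod
    def read(cls, path: str | Path) -> "CategoryMap":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         names=["gene_name", "category"], header=0)
        return cls(mapping=dict(zip(df["gene_name"], df["category"])))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene_name": list(self.mapping), "category": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples or entities on Euclidean distance."""

    linkage: np.ndarray
    leaf_order: list[int]
    labels: list[str]
    axis: str
    method: str

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


@dataclass
class PCAResult:
    coordinates: pd.DataFrame          # samples x components
    variance_explained: np.ndarray


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "samples",
                         method: str = "average") -> ClusterResult:
    """Cluster samples or entities by Euclidean distance.

    scipy's agglomerative linkage is deterministic: equal distances resolve by
    original index order, and the dendrogram places lower-index subtrees left.
    """
    if axis == "samples":
        data = matrix.data.to_numpy(float).T
        labels = matrix.samples
    elif axis == "entities":
        data = matrix.data.to_numpy(float)
        labels = matrix.entities
    else:
        raise ValueError(f"axis must be 'samples' or 'entities', got {axis!r}")
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method=method)
    leaves = hierarchy.leaves_list(link)
    return ClusterResult(linkage=link, leaf_order=[int(i) for i in leaves],
                         labels=labels, axis=axis, method=method)


def pca_coordinates(matrix: ExpressionMatrix, n_components: int = 3) -> PCAResult:
    """Sample scores on the top principal components of entity-centered data.

    Entities are centered across samples (no rescaling: the matrix is already
    normalized to a common log2 scale); scores come from the SVD of the
    samples x entities matrix.
    """
    data = matrix.data.to_numpy(float).T          # samples x entities
    n_samples = data.shape[0]
    if n_samples < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds number of samples {n_samples}"
        )
    centered = data - data.mean(axis=0, keepdims=True)
    total_var = float((centered ** 2).sum())
    if total_var == 0.0:
        raise ValueError("degenerate matrix: no variance across samples")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    coords = pd.DataFrame(
        scores,
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PCAResult(coordinates=coords,
                     variance_explained=(s[:n_components] ** 2) / total_var)


def categorize_updown(entity_list: EntityList, cmap: CategoryMap) -> pd.DataFrame:
    """Up/down member counts per functional category for one pairing."""
    m = entity_list.members
    cats = [cmap.category_of(g) for g in m["gene_name"]]
    df = pd.DataFrame({"category": cats, "direction": m["direction"]})
    table = (
        df.value_counts(["category", "direction"])
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .sort_index()
    )
    table.columns.name = None
    return table.astype(int)


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------

def _require(value, stage: str):
    if value is None:
        raise ValueError(f"missing stage output: {stage}")
    return value


def render_report(
    out_dir: str | Path,
    *,
    filter_report: FilterReport | None = None,
    de_summary: pd.DataFrame | None = None,
    venn_d: dict | None = None,
    venn_wd: dict | None = None,
    concordance_frame: pd.DataFrame | None = None,
    percentages: dict[str, float] | None = None,
    category_tables: dict[str, pd.DataFrame] | None = None,
) -> Path:
    """Write ``report.md`` plus machine-readable TSVs for every section.

    Every number in the report is taken verbatim from the supplied stage
    outputs; a missing stage raises an error naming it.
    """
    filter_report = _require(filter_report, "preprocess (filter report)")
    de_summary = _require(de_summary, "differential (summary)")
    venn_d = _require(venn_d, "differential (D-vs-wild Venn)")
    venn_wd = _require(venn_wd, "differential (WD Venn)")
    concordance_frame = _require(concordance_frame, "inheritance (concordance)")
    percentages = _require(percentages, "inheritance (percentages)")
    category_tables = _require(category_tables, "reporting (category rollups)")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    de_summary.to_csv(out_dir / "de_summary.tsv", sep="\t", index=False)
    concordance_frame.to_csv(out_dir / "concordance.tsv", sep="\t", index=False)
    for pairing, table in category_tables.items():
        table.to_csv(out_dir / f"categories_{pairing}.tsv", sep="\t")

    lines = ["# Run report", ""]
    lines += [
        "## Filtering",
        "",
        f"- entities on array: {filter_report.n_total}",
        f"- entities present: {filter_report.n_present}",
        f"- intensity cutoff: {filter_report.intensity_cutoff:g}",
        f"- presence rule: {filter_report.presence_rule}",
        "",
        "## Significant entities per pairing",
        "",
        de_summary.to_csv(sep="\t", index=False).rstrip(),
        "",
        "## Venn: D vs wild-type lists",
        "",
    ]
    lines += [f"- {' & '.join(k)}: {v}" for k, v in sorted(venn_d.items())]
    lines += ["", "## Venn: WD pairings", ""]
    lines += [f"- {' & '.join(k)}: {v}" for k, v in sorted(venn_wd.items())]
    lines += [
        "",
        "## Inheritance-mode concordance (groups A/B/C)",
        "",
        concordance_frame.to_csv(sep="\t", index=False).rstrip(),
        "",
        "## Group A concordant mode percentages",
        "",
    ]
    lines += [f"- {label}: {pct}%" for label, pct in percentages.items()]
    lines += ["", "## Functional category rollups", ""]
    for pairing in sorted(category_tables):
        lines += [f"### {pairing}", "",
                  category_tables[pairing].to_csv(sep="\t").rstrip(), ""]
    report_path = out_dir / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
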