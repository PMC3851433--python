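"""Raw two-channel scans -> filtered, normalized log2 expression matrix.

Processing order follows standard two-colour practice: channel values are
floored at 1.0 and log2-transformed into per-spot M (log ratio, sample over
reference) and A (mean log intensity); an intensity-dependent dye-bias curve
fitted by LOWESS to the good-flagged spots is subtracted from M; per-sample
records are assembled into a probes x samples matrix; each probe row is
centered on its median across all samples (baseline transformation); finally
entities are filtered on raw intensity and flags.  Intensity checks always use
pre-normalization raw sample-channel values.

The presence rule retained here: a probe is kept iff its raw sample-channel
signal reaches the cutoff in every replicate of at least one genotype group
(protecting group-specific expression) and it is flagged good in at least 75%
of all samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from troutarray.design import GroupDesign
from troutarray.simulate import ArrayScan, FLAG_GOOD, SCAN_COLUMNS

DEFAULT_CUTOFF = 300.0
DEFAULT_SPAN = 0.3
DEFAULT_GOOD_FLAG_FRACTION = 0.75
MIN_GOOD_SPOTS = 10


class ScanFormatError(ValueError):
    """A scan file violates the expected dialect."""


@dataclass
class ProbeRecords:
    """Per-sample M/A values: columns ``probe_id, gene_name, M, A, flag``."""

    sample_id: str
    group: str
    table: pd.DataFrame


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, probes x samples, with design attached."""

    data: pd.DataFrame                      # index probe_id, columns sample_id
    gene_names: pd.Series                   # probe_id -> gene_name
    design: GroupDesign
    provenance: list[str] = field(default_factory=list)

    @property
    def entities(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def group_columns(self, group: str) -> pd.DataFrame:
        return self.data[self.design.samples_in(group)]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# provenance: " + " | ".join(self.provenance) + "\n")
            out = self.data.copy()
            out.insert(0, "gene_name", self.gene_names.reindex(out.index))
            out.index.name = "entity_id"
            out.to_csv(fh, sep="\t", float_format="%.6f")

    @classmethod
    def read(cls, path: str | Path, design: GroupDesign) -> "ExpressionMatrix":
        path = Path(path)
        provenance: list[str] = []
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# provenance:"):
                provenance = [s.strip() for s in
                              first.removeprefix("# provenance:").split("|")]
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="entity_id")
        gene_names = df.pop("gene_name")
        return cls(data=df, gene_names=gene_names, design=design,
                   provenance=provenance)


@dataclass
class FilterReport:
    """Counts and rules applied by :func:`filter_entities`."""

    n_total: int
    n_present: int
    intensity_cutoff: float
    presence_rule: str

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_total\t{self.n_total}\n")
            fh.write(f"n_present\t{self.n_present}\n")
            fh.write(f"intensity_cutoff\t{self.intensity_cutoff:g}\n")
            fh.write(f"presence_rule\t{self.presence_rule}\n")


# ---------------------------------------------------------------------------
# per-scan steps
# ---------------------------------------------------------------------------

def read_scan(path: str | Path, sample_id: str | None = None,
              group: str = "") -> ArrayScan:
    """Parse one tab-delimited scan table (``probe_id gene_name ch1 ch2 flag``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_name": str,
                                                "flag": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ScanFormatError(f"{path}: no probes (empty file)") from None
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ScanFormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ScanFormatError(f"{path}: no probes")
    for col in ("ch1", "ch2"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ScanFormatError(
                f"{path}: non-numeric {col} intensity at line(s) {lines}"
            )
        if (values < 0).any() or not np.isfinite(values).all():
            raise ScanFormatError(f"{path}: {col} intensities must be finite and >= 0")
        df[col] = values
    return ArrayScan(sample_id=sample_id or path.stem, group=group,
                     probes=df[SCAN_COLUMNS])


def threshold_and_log(scan: ArrayScan) -> ProbeRecords:
    """Floor channels at 1.0, then form M = log2(ch2/ch1), A = mean log2."""
    ch1 = np.maximum(scan.probes["ch1"].to_numpy(float), 1.0)
    ch2 = np.maximum(scan.probes["ch2"].to_numpy(float), 1.0)
    l1, l2 = np.log2(ch1), np.log2(ch2)
    table = pd.DataFrame(
        {
            "probe_id": scan.probes["probe_id"],
            "gene_name": scan.probes["gene_name"],
            "M": l2 - l1,
            "A": 0.5 * (l2 + l1),
            "flag": scan.probes["flag"],
        }
    )
    return ProbeRecords(sample_id=scan.sample_id, group=scan.group, table=table)


def lowess_normalize(records: ProbeRecords, span: float = DEFAULT_SPAN) -> ProbeRecords:
    """Subtract a LOWESS fit of M on A (fit to good spots, applied to all).

    Flagged spots receive the correction via interpolation of the fitted
    curve but never influence the fit, so downstream matrices stay
    rectangular.
    """
    t = records.table
    good = (t["flag"] == FLAG_GOOD).to_numpy()
    if good.sum() < MIN_GOOD_SPOTS:
        raise ValueError(
            f"insufficient spots for normalization: {int(good.sum())} good spots "
            f"in sample {records.sample_id} (need >= {MIN_GOOD_SPOTS})"
        )
    a = t["A"].to_numpy(float)
    m = t["M"].to_numpy(float)
    a_good, m_good = a[good], m[good]
    delta = 0.01 * (a_good.max() - a_good.min())
    fit = sm_lowess(m_good, a_good, frac=span, delta=delta, return_sorted=True)
    correction = np.interp(a, fit[:, 0], fit[:, 1])
    out = t.copy()
    out["M"] = m - correction
    return ProbeRecords(sample_id=records.sample_id, group=records.group, table=out)


# ---------------------------------------------------------------------------
# matrix assembly and filtering
# ---------------------------------------------------------------------------

def assemble_matrix(per_sample: list[ProbeRecords], design: GroupDesign,
                    provenance: list[str] | None = None) -> ExpressionMatrix:
    """Align per-sample M values into a probes x samples matrix by probe_id."""
    if not per_sample:
        raise ValueError("no samples to assemble")
    by_id = {r.sample_id: r for r in per_sample}
    missing = [s for s in design.samples if s not in by_id]
    if missing:
        raise ValueError(f"design samples without records: {missing}")
    ref = by_id[design.samples[0]].table["probe_id"]
    columns = {}
    for sample in design.samples:
        t = by_id[sample].table
        if len(t) != len(ref) or not (t["probe_id"].to_numpy() == ref.to_numpy()).all():
            extra = sorted(set(t["probe_id"]) ^ set(ref))
            raise ValueError(
                f"probe set mismatch between {design.samples[0]} and {sample}: "
                f"{extra[:10]}{'...' if len(extra) > 10 else ''}"
            )
        columns[sample] = t["M"].to_numpy(float)
    data = pd.DataFrame(columns, index=pd.Index(ref, name="probe_id"))
    gene_names = by_id[design.samples[0]].table.set_index("probe_id")["gene_name"]
    return ExpressionMatrix(data=data, gene_names=gene_names, design=design,
                            provenance=list(provenance or []))


def baseline_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Baseline transformation: subtract each probe's median across all samples.

    The median of an even number of samples is the mean of the two middle
    values, so row medians are exactly zero afterwards (idempotent).
    """
    med = matrix.data.median(axis=1)
    return ExpressionMatrix(
        data=matrix.data.sub(med, axis=0),
        gene_names=matrix.gene_names,
        design=matrix.design,
        provenance=matrix.provenance + ["baseline_center(median across samples)"],
    )


def filter_entities(
    matrix: ExpressionMatrix,
    raw_scans: list[ArrayScan],
    cutoff: float = DEFAULT_CUTOFF,
    good_flag_fraction: float = DEFAULT_GOOD_FLAG_FRACTION,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop probes failing the intensity/flag presence rule.

    Presence requires raw sample-channel (ch2) signal >= ``cutoff`` in every
    replicate of at least one genotype group, and a good flag in at least
    ``good_flag_fraction`` of all samples.
    """
    if cutoff <= 0:
        raise ValueError(f"intensity cutoff must be positive, got {cutoff}")
    by_id = {s.sample_id: s for s in raw_scans}
    missing = [s for s in matrix.samples if s not in by_id]
    if missing:
        raise ValueError(f"raw scans missing for samples: {missing}")

    idx = matrix.data.index
    ch2 = pd.DataFrame(
        {s: by_id[s].probes.set_index("probe_id")["ch2"].reindex(idx)
         for s in matrix.samples}
    )
    goodflag = pd.DataFrame(
        {s: (by_id[s].probes.set_index("probe_id")["flag"] == FLAG_GOOD).reindex(idx)
         for s in matrix.samples}
    )

    present = np.zeros(len(idx), dtype=bool)
    for g in matrix.design.groups:
        cols = matrix.design.samples_in(g)
        present |= (ch2[cols] >= cutoff).all(axis=1).to_numpy()
    flag_ok = (goodflag.mean(axis=1) >= good_flag_fraction).to_numpy()
    keep = present & flag_ok

    rule = (
        f"ch2 >= {cutoff:g} in all replicates of >=1 group AND flag G in "
        f">= {good_flag_fraction:.0%} of samples"
    )
    report = FilterReport(
        n_total=len(idx),
        n_present=int(keep.sum()),
        intensity_cutoff=cutoff,
        presence_rule=rule,
    )
    filtered = ExpressionMatrix(
        data=matrix.data.loc[keep],
        gene_names=matrix.gene_names.reindex(matrix.data.index[keep]),
        design=matrix.design,
        provenance=matrix.provenance + [f"filter_entities({rule})"],
    )
    return filtered, report


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def preprocess_scans(
    scans: list[ArrayScan],
    design: GroupDesign,
    cutoff: float = DEFAULT_CUTOFF,
    span: float = DEFAULT_SPAN,
    good_flag_fraction: float = DEFAULT_GOOD_FLAG_FRACTION,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Full preprocessing: threshold/log2 -> LOWESS -> assemble -> center -> filter."""
    records = [lowess_normalize(threshold_and_log(s), span=span) for s in scans]
    provenance = [
        "threshold(1.0) + log2",
        f"lowess_normalize(span={span:g}, good spots only)",
    ]
    matrix = assemble_matrix(records, design, provenance=provenance)
    matrix = baseline_center(matrix)
    return filter_entities(matrix, scans, cutoff=cutoff,
                           good_flag_fraction=good_flag_fraction)
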