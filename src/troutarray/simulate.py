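"""Synthetic two-channel reference-design microarray experiment.

Generates per-gene ground truth (inheritance mode and group means on the log2
scale) and one quantified scan table per fish, emulating a 44K salmonid
oligo-array experiment with four genotype groups (Wa, Ws, D, WD), six
biological replicates per group, and a pooled size-matched-wild (Ws) reference
in the opposite dye channel.

The measurement model, per spot:

* sample channel  ``ch2 = 2**(mu_group + fish_noise + spot_noise) + background``
* reference channel ``ch1 = 2**(ref_pool + spot_noise') + background``
* an intensity-dependent dye distortion multiplies ``ch2`` by
  ``2**bias(A)`` where ``bias`` is a decreasing logistic in the mean log2
  intensity A (low-intensity inflation), amplitude ``dye_bias_amplitude``.

Fish-level biological noise is normal on the log2 scale with
``sd = log2(1 + biological_cv)``; spot-level technical noise uses half that
spread and is independent across replicate probes of the same gene.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from troutarray.design import GROUPS, GroupDesign

#: genotype-effect modes assignable in the generator
EFFECT_MODES = ("additive", "D-dominant", "D-recessive", "overdominant", "no-effect")
#: all truth modes (stage-only = Wa-vs-Ws developmental-stage difference only)
TRUTH_MODES = EFFECT_MODES + ("stage-only",)

FLAG_GOOD, FLAG_BAD, FLAG_ABSENT = "G", "B", "A"

SCAN_COLUMNS = ["probe_id", "gene_name", "ch1", "ch2", "flag"]
TRUTH_COLUMNS = ["gene_id", "mode", "mu_W", "mu_WD", "mu_D", "delta_stage"]

# shape of the low-intensity dye distortion: bias(A) = amp / (1 + exp((A - A0)/s))
_DYE_BIAS_MIDPOINT = 8.0
_DYE_BIAS_SCALE = 1.5


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _default_mode_weights() -> dict[str, float]:
    # mirrors the rough additive/dominant/recessive balance seen among
    # genotype-affected liver mRNAs; overdominance off by default
    return {
        "additive": 0.35,
        "D-dominant": 0.25,
        "D-recessive": 0.40,
        "overdominant": 0.0,
        "no-effect": 0.0,
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic experiment.

    Defaults reproduce the study geometry: 4 groups x 6 fish on a 43,689-spot
    array, a pooled Ws reference, intensity-dependent dye bias and a minority
    of genes expressed above the detection cutoff.
    """

    n_genes: int = 43_689
    replicate_probe_fraction: float = 0.1
    n_per_group: int = 6
    groups: tuple[str, ...] = GROUPS
    fraction_affected: float = 0.1
    mode_weights: dict[str, float] = field(default_factory=_default_mode_weights)
    effect_size_log2: float = 2.0
    biological_cv: float = 0.1
    dye_bias_amplitude: float = 0.5
    background_mean: float = 50.0
    flagged_fraction: float = 0.05
    stage_effect_fraction: float = 0.02
    expressed_fraction: float = 0.25
    baseline_log2_mean: float = 12.0
    baseline_log2_sd: float = 1.5
    unexpressed_log2_mean: float = 5.0
    unexpressed_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be a positive count")
        if self.n_per_group <= 0:
            raise ConfigurationError("n_per_group must be a positive count")
        for name in (
            "replicate_probe_fraction",
            "fraction_affected",
            "flagged_fraction",
            "stage_effect_fraction",
            "expressed_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_affected + self.stage_effect_fraction > 1.0:
            raise ConfigurationError(
                "fraction_affected + stage_effect_fraction must not exceed 1"
            )
        if set(self.mode_weights) != set(EFFECT_MODES):
            raise ConfigurationError(
                f"mode_weights must have keys {EFFECT_MODES}, "
                f"got {sorted(self.mode_weights)}"
            )
        if any(w < 0 for w in self.mode_weights.values()):
            raise ConfigurationError("mode_weights must be non-negative")
        total = sum(self.mode_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"mode_weights must sum to 1, got {total!r}")
        for name in ("biological_cv", "dye_bias_amplitude", "background_mean",
                     "effect_size_log2", "baseline_log2_sd", "unexpressed_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    # ---- config file round trip -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "simulation" in data:  # nested section permitted
            data = data["simulation"]
        if "groups" in data:
            data["groups"] = tuple(data["groups"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"unrecognised configuration key: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["groups"] = list(self.groups)
        with open(path, "w") as fh:
            yaml.safe_dump({"simulation": data}, fh, sort_keys=False)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one gene: inheritance mode and log2 group means.

    ``mu_W`` is the wild baseline (equal to the Ws mean; the Wa mean is
    ``mu_W + delta_stage``); ``mu_WD`` and ``mu_D`` are the hybrid and
    domesticated means.
    """

    gene_id: str
    mode: str
    mu_W: float
    mu_WD: float
    mu_D: float
    delta_stage: float

    def group_mean(self, group: str) -> float:
        return {
            "Ws": self.mu_W,
            "Wa": self.mu_W + self.delta_stage,
            "D": self.mu_D,
            "WD": self.mu_WD,
        }[group]


@dataclass
class ArrayScan:
    """One sample's quantified two-channel scan.

    ``probes`` has columns ``probe_id, gene_name, ch1, ch2, flag`` in the fixed
    array order shared by every scan of an experiment; ch1 is the pooled-
    reference channel, ch2 the individual-fish channel.
    """

    sample_id: str
    group: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCAN_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"scan {self.sample_id}: missing columns {missing}")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def simulate_truth(config: SimulationConfig) -> list[TruthRecord]:
    """Draw per-gene modes and log2 group means.

    A gene receives a genotype mode from ``mode_weights`` with probability
    ``fraction_affected``, a pure developmental-stage (Wa-vs-Ws) difference
    with probability ``stage_effect_fraction``, and is otherwise unaffected.
    Mode-mean algebra is exact: additive hybrids sit at the parental midpoint,
    D-dominant at the D mean, D-recessive at the wild mean, overdominant
    beyond the D mean by half the parental difference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_genes

    u = rng.uniform(size=n)
    modes = np.full(n, "no-effect", dtype=object)
    affected = u < config.fraction_affected
    stage_only = (~affected) & (u < config.fraction_affected + config.stage_effect_fraction)
    weights = np.array([config.mode_weights[m] for m in EFFECT_MODES])
    drawn = rng.choice(len(EFFECT_MODES), size=n, p=weights / weights.sum())
    modes[affected] = np.array(EFFECT_MODES, dtype=object)[drawn[affected]]
    modes[stage_only] = "stage-only"

    expressed = rng.uniform(size=n) < config.expressed_fraction
    mu_W = np.where(
        expressed,
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n),
        rng.normal(config.unexpressed_log2_mean, config.unexpressed_log2_sd, size=n),
    )
    sign = rng.choice([-1.0, 1.0], size=n)
    delta = config.effect_size_log2 * sign

    mu_D = mu_W.copy()
    mu_WD = mu_W.copy()
    delta_stage = np.zeros(n)
    for i, mode in enumerate(modes):
        if mode in ("additive", "D-dominant", "D-recessive", "overdominant"):
            mu_D[i] = mu_W[i] + delta[i]
            if mode == "additive":
                mu_WD[i] = (mu_W[i] + mu_D[i]) / 2.0
            elif mode == "D-dominant":
                mu_WD[i] = mu_D[i]
            elif mode == "D-recessive":
                mu_WD[i] = mu_W[i]
            else:  # overdominant: outside the parental range
                mu_WD[i] = mu_W[i] + 1.5 * delta[i]
        elif mode == "stage-only":
            delta_stage[i] = delta[i]

    width = max(5, len(str(n)))
    return [
        TruthRecord(
            gene_id=f"gene{i + 1:0{width}d}",
            mode=modes[i],
            mu_W=float(mu_W[i]),
            mu_WD=float(mu_WD[i]),
            mu_D=float(mu_D[i]),
            delta_stage=float(delta_stage[i]),
        )
        for i in range(n)
    ]


def truth_from_modes(modes: list[str], config: SimulationConfig) -> list[TruthRecord]:
    """Build truth records with *prescribed* modes (one gene per entry).

    Baselines are drawn as for expressed genes; the effect magnitude is
    ``effect_size_log2`` with random sign.  Used for parameter-recovery
    studies where exact per-mode gene counts are required.
    """
    unknown = sorted(set(modes) - set(TRUTH_MODES))
    if unknown:
        raise ConfigurationError(f"unknown modes {unknown}; expected {TRUTH_MODES}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    n = len(modes)
    mu_W = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    width = max(5, len(str(n)))
    records = []
    for i, mode in enumerate(modes):
        w = float(mu_W[i])
        delta = config.effect_size_log2 * float(sign[i])
        d = wd = w
        ds = 0.0
        if mode in ("additive", "D-dominant", "D-recessive", "overdominant"):
            d = w + delta
            wd = {"additive": (w + d) / 2.0, "D-dominant": d,
                  "D-recessive": w, "overdominant": w + 1.5 * delta}[mode]
        elif mode == "stage-only":
            ds = delta
        records.append(TruthRecord(gene_id=f"gene{i + 1:0{width}d}", mode=mode,
                                   mu_W=w, mu_WD=wd, mu_D=d, delta_stage=ds))
    return records


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truth], columns=TRUTH_COLUMNS)


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    truth_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _probe_layout(truth: list[TruthRecord], config: SimulationConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Array layout: one probe per gene plus duplicate probes for a random
    subset of genes (same gene_name, distinct probe_id, appended after the
    primary block)."""
    n = len(truth)
    gene_idx = list(range(n))
    dup = np.flatnonzero(rng.uniform(size=n) < config.replicate_probe_fraction)
    gene_idx.extend(int(i) for i in dup)
    width = max(6, len(str(len(gene_idx))))
    return pd.DataFrame(
        {
            "probe_id": [f"P{k + 1:0{width}d}" for k in range(len(gene_idx))],
            "gene_idx": gene_idx,
            "gene_name": [truth[i].gene_id for i in gene_idx],
        }
    )


def simulate_scans(truth: list[TruthRecord], config: SimulationConfig) -> list[ArrayScan]:
    """Simulate one two-channel scan per fish (``len(groups) * n_per_group``).

    The reference channel models a single pooled Ws sample (pool mean of the
    Ws truth plus pool noise shrunk by sqrt(n_per_group)), re-labelled per
    array with independent spot noise.
    """
    if not truth:
        raise ValueError("no probes: truth is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    layout = _probe_layout(truth, config, rng)
    gi = layout["gene_idx"].to_numpy()
    n_spots = len(layout)

    sd_bio = np.log2(1.0 + config.biological_cv)
    sd_tech = 0.5 * sd_bio

    mu = {g: np.array([t.group_mean(g) for t in truth]) for g in config.groups}
    # one pooled reference shared by every array
    ref_pool = mu["Ws"] + rng.normal(0.0, sd_bio / np.sqrt(config.n_per_group),
                                     size=len(truth))

    design = GroupDesign.balanced(config.n_per_group, config.groups)
    scans: list[ArrayScan] = []
    for sample in design.samples:
        group = design.group_of[sample]
        fish = mu[group] + rng.normal(0.0, sd_bio, size=len(truth))
        log_ch2 = fish[gi] + rng.normal(0.0, sd_tech, size=n_spots)
        log_ch1 = ref_pool[gi] + rng.normal(0.0, sd_tech, size=n_spots)
        ch2 = np.exp2(log_ch2)
        ch1 = np.exp2(log_ch1)
        if config.background_mean > 0:
            ch2 = ch2 + rng.gamma(4.0, config.background_mean / 4.0, size=n_spots)
            ch1 = ch1 + rng.gamma(4.0, config.background_mean / 4.0, size=n_spots)
        if config.dye_bias_amplitude > 0:
            a = 0.5 * (np.log2(np.maximum(ch1, 1.0)) + np.log2(np.maximum(ch2, 1.0)))
            bias = config.dye_bias_amplitude / (
                1.0 + np.exp((a - _DYE_BIAS_MIDPOINT) / _DYE_BIAS_SCALE)
            )
            ch2 = ch2 * np.exp2(bias)

        flag = np.full(n_spots, FLAG_GOOD, dtype=object)
        bad = rng.uniform(size=n_spots) < config.flagged_fraction
        absent = bad & (rng.uniform(size=n_spots) < 0.2)
        flag[bad] = FLAG_BAD
        flag[absent] = FLAG_ABSENT

        probes = pd.DataFrame(
            {
                "probe_id": layout["probe_id"],
                "gene_name": layout["gene_name"],
                "ch1": ch1,
                "ch2": ch2,
                "flag": flag,
            }
        )
        scans.append(ArrayScan(sample_id=sample, group=group, probes=probes))
    return scans


def write_scans(scans: list[ArrayScan], directory: str | Path) -> list[Path]:
    """Write one tab-delimited scan table per sample as ``<sample_id>.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for scan in scans:
        if scan.probes.empty:
            raise ValueError(f"scan {scan.sample_id}: no probes")
        path = directory / f"{scan.sample_id}.tsv"
        buf = io.StringIO()
        # %.17g guarantees a lossless float64 round trip through text
        scan.probes[SCAN_COLUMNS].to_csv(buf, sep="\t", index=False,
                                         float_format="%.17g")
        path.write_text(buf.getvalue())
        paths.append(path)
    return paths
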