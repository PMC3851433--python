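"""Sample-to-group design for the four-genotype trout experiment.

Groups follow the study layout: two wild-type comparator groups (Wa,
age-matched; Ws, size-matched), a domesticated strain (D) and the F1
wild x domesticated hybrid (WD).  The domesticated-genome dose used as the
regression covariate is 0% for pure wild, 50% for the hybrid and 100% for
the domesticated strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: canonical group order
GROUPS: tuple[str, ...] = ("Wa", "Ws", "D", "WD")

#: fraction of domesticated genome per group, in percent
DOSE_OF_GROUP: dict[str, int] = {"Wa": 0, "Ws": 0, "WD": 50, "D": 100}

#: the six unordered group pairings, in reporting order
PAIRINGS: tuple[tuple[str, str], ...] = (
    ("D", "Wa"),
    ("D", "Ws"),
    ("WD", "Wa"),
    ("WD", "Ws"),
    ("WD", "D"),
    ("Wa", "Ws"),
)


@dataclass
class GroupDesign:
    """Ordered samples and their genotype-group assignment."""

    samples: list[str]
    group_of: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        unknown = sorted({g for g in self.group_of.values()} - set(GROUPS))
        if unknown:
            raise ValueError(f"unknown group labels {unknown}; expected {GROUPS}")
        for g in GROUPS:
            if not self.samples_in(g):
                raise ValueError(f"group {g!r} has no samples")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def dose_of(self, sample: str) -> int:
        return DOSE_OF_GROUP[self.group_of[sample]]

    @property
    def groups(self) -> tuple[str, ...]:
        return GROUPS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "group": [self.group_of[s] for s in self.samples],
                "dose_pct": [self.dose_of(s) for s in self.samples],
            }
        )

    @classmethod
    def balanced(cls, n_per_group: int, groups: tuple[str, ...] = GROUPS) -> "GroupDesign":
        """Balanced design with ``n_per_group`` fish per genotype group."""
        samples, group_of = [], {}
        for g in groups:
            for i in range(1, n_per_group + 1):
                sid = f"{g}_{i:02d}"
                samples.append(sid)
                group_of[sid] = g
        return cls(samples=samples, group_of=group_of)

    @classmethod
    def read_sample_sheet(cls, path: str | Path) -> "GroupDesign":
        """Read a tab-delimited sheet with columns ``sample_id`` and ``group``."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"sample_id", "group"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"sample sheet {path} must have columns {sorted(required)}, "
                f"found {list(df.columns)}"
            )
        return cls(
            samples=df["sample_id"].tolist(),
            group_of=dict(zip(df["sample_id"], df["group"])),
        )

    def write_sample_sheet(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
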