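import numpy as np
import pandas as pd
import pytest

from troutarray.design import GROUPS, GroupDesign
from troutarray.preprocess import ExpressionMatrix


def build_matrix(entity_values: dict[str, dict[str, list[float]]],
                 gene_names: dict[str, str] | None = None) -> ExpressionMatrix:
    """Construct an ExpressionMatrix from {entity: {group: per-fish values}}."""
    first = next(iter(entity_values.values()))
    n_per_group = len(next(iter(first.values())))
    design = GroupDesign.balanced(n_per_group)
    rows = {}
    for entity, by_group in entity_values.items():
        row = []
        for g in GROUPS:
            vals = by_group[g]
            assert len(vals) == n_per_group
            row.extend(vals)
        rows[entity] = row
    data = pd.DataFrame.from_dict(rows, orient="index", columns=design.samples,
                                  dtype=float)
    data.index.name = "probe_id"
    names = pd.Series({e: (gene_names or {}).get(e, e) for e in rows},
                      name="gene_name")
    return ExpressionMatrix(data=data, gene_names=names, design=design,
                            provenance=["built-in-test"])


def noisy_pattern(rng: np.random.Generator, means: dict[str, float],
                  n: int = 6, sd: float = 0.15) -> dict[str, list[float]]:
    """Per-group fish values around the given group means."""
    return {g: list(rng.normal(means[g], sd, size=n)) for g in GROUPS}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
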