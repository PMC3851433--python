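"""Inheritance-mode classification of hybrid mRNA regulation.

For each differentially expressed entity the hybrid (WD) is compared with a
wild parent proxy (the chosen reference group, Wa or Ws) and the domesticated
parent (D), using Tukey pairwise p-values from an ANOVA re-run on the combined
D-vs-wild significant list:

* both WD-vs-W and WD-vs-D significant      -> additive
* only WD-vs-W significant                  -> D-dominant (hybrid resembles D)
* only WD-vs-D significant                  -> D-recessive (hybrid resembles W)
* neither significant                       -> linear regression of non-log
  expression on domesticated-genome dose (0/50/100%); a slope significantly
  different from zero gives resembling-additive (counted with additive),
  otherwise no-effect (Ne).

Classification is done independently with each wild group as reference;
concordance counts entities receiving the same label either way, within the
shared/unique partition (groups A/B/C) of the two D-vs-wild lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from troutarray.design import DOSE_OF_GROUP
from troutarray.differential import (EntityList, _anova_rows, _group_slices,
                                     bh_adjust, tukey_pairwise)
from troutarray.preprocess import ExpressionMatrix
from troutarray.util import round_half_up

LABELS = ("additive", "D-dominant", "D-recessive", "resembling-additive", "no-effect")
#: Table-style short bins; resembling-additive is counted with additive
SHORT_LABEL = {
    "additive": "a",
    "resembling-additive": "a",
    "D-dominant": "d",
    "D-recessive": "r",
    "no-effect": "Ne",
}
SHORT_BINS = ("r", "d", "a", "Ne")


@dataclass(frozen=True)
class InheritanceCall:
    """One entity's mode call under one wild reference group."""

    entity_id: str
    reference_group: str
    label: str
    basis: str
    slope: float | None = None
    slope_p: float | None = None

    @property
    def short_label(self) -> str:
        return SHORT_LABEL[self.label]


# ---------------------------------------------------------------------------
# regression fallback
# ---------------------------------------------------------------------------

def regression_fallback(
    entity: str,
    matrix: ExpressionMatrix,
    reference_group: str,
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Slope test of non-log expression on domesticated-genome dose.

    Uses every individual fish of the wild reference, hybrid and domesticated
    groups at doses 0/50/100; expression is back-transformed (2**log2 value).
    A numerically perfect zero-residual fit with non-zero slope is declared
    significant.  Returns ``(slope per dose %, two-sided p, label)``.
    """
    design = matrix.design
    doses, values = [], []
    for g in (reference_group, "WD", "D"):
        cols = design.samples_in(g)
        if not cols:
            raise ValueError(f"missing group data for {g!r}")
        v = matrix.data.loc[entity, cols].to_numpy(float)
        values.extend(np.exp2(v))
        doses.extend([DOSE_OF_GROUP[g]] * len(cols))
    doses = np.asarray(doses, float)
    values = np.asarray(values, float)

    if np.allclose(values, values[0]):
        return 0.0, 1.0, "no-effect"
    res = stats.linregress(doses, values)
    slope, p = float(res.slope), float(res.pvalue)
    fitted = res.intercept + res.slope * doses
    rss = float(((values - fitted) ** 2).sum())
    if rss <= 1e-12 * float(((values - values.mean()) ** 2).sum()):
        p = 0.0 if slope != 0.0 else 1.0  # perfect linear fit
    label = "resembling-additive" if p <= alpha else "no-effect"
    return slope, p, label


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_modes(
    matrix: ExpressionMatrix,
    entities: list[str],
    reference_group: str,
    alpha: float = 0.05,
) -> dict[str, InheritanceCall]:
    """Classify ``entities`` under one wild reference group.

    Re-runs the omnibus ANOVA across all four groups on exactly the supplied
    entity list, applies BH within that list, and computes Tukey pairwise
    p-values for entities passing BH; the WD-vs-reference and WD-vs-D Tukey
    contrasts at raw ``alpha`` drive the decision tree.
    """
    if reference_group not in ("Wa", "Ws"):
        raise ValueError(f"reference_group must be 'Wa' or 'Ws', got {reference_group!r}")
    missing = [e for e in entities if e not in matrix.data.index]
    if missing:
        raise ValueError(f"entities not in matrix: {missing[:5]}")
    design = matrix.design
    groups = list(design.groups)
    cols = [design.samples_in(g) for g in groups]
    sub = matrix.data.loc[entities]
    values = sub[[s for c in cols for s in c]].to_numpy(float)
    slices = _group_slices([len(c) for c in cols])

    _, p = _anova_rows(values, slices)
    q = bh_adjust(p)

    calls: dict[str, InheritanceCall] = {}
    for row, entity in enumerate(entities):
        sig_w = sig_d = False
        if q[row] <= alpha:
            by_group = {g: values[row, sl] for g, sl in zip(groups, slices)}
            pp = tukey_pairwise(by_group)
            sig_w = pp[("WD", reference_group)] <= alpha
            sig_d = pp[("WD", "D")] <= alpha
        basis = (f"WD-vs-{reference_group}:{'sig' if sig_w else 'ns'},"
                 f"WD-vs-D:{'sig' if sig_d else 'ns'}")
        if sig_w and sig_d:
            calls[entity] = InheritanceCall(entity, reference_group, "additive", basis)
        elif sig_w:
            calls[entity] = InheritanceCall(entity, reference_group, "D-dominant", basis)
        elif sig_d:
            calls[entity] = InheritanceCall(entity, reference_group, "D-recessive", basis)
        else:
            slope, slope_p, label = regression_fallback(
                entity, matrix, reference_group, alpha=alpha
            )
            calls[entity] = InheritanceCall(entity, reference_group, label, basis,
                                            slope=slope, slope_p=slope_p)
    return calls


def classify_mode(
    entity: str,
    matrix: ExpressionMatrix,
    reference_group: str,
    alpha: float = 0.05,
) -> InheritanceCall:
    """Single-entity convenience wrapper around :func:`classify_modes`."""
    return classify_modes(matrix, [entity], reference_group, alpha=alpha)[entity]


def calls_frame(calls: dict[str, InheritanceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "entity_id": [c.entity_id for c in calls.values()],
            "reference": [c.reference_group for c in calls.values()],
            "label": [c.label for c in calls.values()],
            "basis": [c.basis for c in calls.values()],
            "slope": [np.nan if c.slope is None else c.slope for c in calls.values()],
            "slope_p": [np.nan if c.slope_p is None else c.slope_p
                        for c in calls.values()],
        }
    )


# ---------------------------------------------------------------------------
# partition and concordance
# ---------------------------------------------------------------------------

def partition_groups(
    list_d_wa: EntityList | set,
    list_d_ws: EntityList | set,
) -> dict[str, set]:
    """Venn split of the two D-vs-wild lists: A shared, B Wa-only, C Ws-only."""
    wa = list_d_wa.ids if isinstance(list_d_wa, EntityList) else set(list_d_wa)
    ws = list_d_ws.ids if isinstance(list_d_ws, EntityList) else set(list_d_ws)
    return {"A": wa & ws, "B": wa - ws, "C": ws - wa}


@dataclass
class ConcordanceTable:
    """Mode counts per partition group, per reference, plus concordant counts."""

    counts: dict[str, dict[str, dict[str, int]]]      # group -> ref -> bin -> n
    concordant: dict[str, dict[str, int]]             # group -> bin -> n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in ("A", "B", "C"):
            for ref in ("Wa", "Ws"):
                rows.append({"group": group, "reference": ref,
                             **self.counts[group][ref]})
            rows.append({"group": group, "reference": "Concordance",
                         **self.concordant[group]})
        return pd.DataFrame(rows, columns=["group", "reference", *SHORT_BINS])


def concordance(
    calls_wa: dict[str, InheritanceCall],
    calls_ws: dict[str, InheritanceCall],
    partition: dict[str, set],
) -> ConcordanceTable:
    """Tabulate mode bins under both references and their agreement per group."""
    counts: dict[str, dict[str, dict[str, int]]] = {}
    concordant: dict[str, dict[str, int]] = {}
    for group, entities in partition.items():
        missing = [e for e in entities if e not in calls_wa or e not in calls_ws]
        if missing:
            raise ValueError(
                f"entities in group {group} classified under one reference only: "
                f"{sorted(missing)[:5]}"
            )
        c_wa = {b: 0 for b in SHORT_BINS}
        c_ws = {b: 0 for b in SHORT_BINS}
        c_both = {b: 0 for b in SHORT_BINS}
        for e in entities:
            a, b = calls_wa[e].short_label, calls_ws[e].short_label
            c_wa[a] += 1
            c_ws[b] += 1
            if a == b:
                c_both[a] += 1
        counts[group] = {"Wa": c_wa, "Ws": c_ws}
        concordant[group] = c_both
    return ConcordanceTable(counts=counts, concordant=concordant)


def summarize_percentages(concordant_counts: dict[str, int],
                          decimals: int = 1) -> dict[str, float]:
    """Each bin's share of the concordant total, rounded half-up."""
    if any(v < 0 for v in concordant_counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(concordant_counts.values())
    if total == 0:
        raise ValueError("all counts are zero")
    return {
        label: round_half_up(100.0 * n / total, decimals)
        for label, n in concordant_counts.items()
    }
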