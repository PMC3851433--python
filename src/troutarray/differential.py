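"""Group-pairwise differential expression: ANOVA, Tukey HSD, BH, fold change.

The testing composition: an equal-variance one-way ANOVA across the four
genotype groups per entity, Benjamini-Hochberg step-up correction across
entities on the omnibus p-values, then Tukey HSD pairwise tests (studentized
range with pooled within-group variance; Tukey-Kramer for unequal n) on the
entities passing BH.  A pairing's significant-entity list requires the
BH-adjusted omnibus, the pairwise Tukey p and a linear fold-change threshold
simultaneously.  An alternative composition (BH across entities applied per
pairing to the Tukey p-values) is available behind ``bh_on='pairwise'``.

Fold change is computed from group means of the normalized log2 values,
``fc = 2**(mean(condition1) - mean(condition2))``; per-gene median centering
cancels in this difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from troutarray.design import PAIRINGS
from troutarray.preprocess import ExpressionMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_FC = 2.0


def _pair_key(g1: str, g2: str) -> str:
    return f"{g1}_vs_{g2}"


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def anova_omnibus(groups: list[np.ndarray]) -> tuple[float, float]:
    """Equal-variance one-way ANOVA F statistic and upper-tail p for one entity.

    Degenerate inputs: zero between- and within-group variance gives F = 0,
    p = 1; zero within- with non-zero between-group variance gives p = 0.
    """
    f, p = _anova_rows(np.concatenate(groups)[None, :],
                       _group_slices([len(g) for g in groups]))
    return float(f[0]), float(p[0])


def _group_slices(sizes: list[int]) -> list[slice]:
    for n in sizes:
        if n < 2:
            raise ValueError(f"each group needs >= 2 observations, got n={n}")
    if len(sizes) < 2:
        raise ValueError("need >= 2 groups")
    edges = np.cumsum([0] + list(sizes))
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _anova_rows(values: np.ndarray, slices: list[slice]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA over the rows of ``values`` (rows = entities)."""
    k = len(slices)
    n_total = values.shape[1]
    grand = values.mean(axis=1)
    ssb = np.zeros(len(values))
    ssw = np.zeros(len(values))
    for sl in slices:
        block = values[:, sl]
        m = block.mean(axis=1)
        ssb += block.shape[1] * (m - grand) ** 2
        ssw += ((block - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    # conventions for zero-variance rows
    null_rows = np.isclose(ssb, 0.0) & np.isclose(ssw, 0.0)
    f[null_rows], p[null_rows] = 0.0, 1.0
    exact_rows = np.isclose(ssw, 0.0) & ~null_rows
    f[exact_rows], p[exact_rows] = np.inf, 0.0
    return f, p


def tukey_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Tukey HSD p-value per unordered group pair (Tukey-Kramer for unequal n).

    The studentized-range statistic uses the pooled within-group variance of
    *all* groups; p-values are symmetric in pair order.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], float) for g in labels]
    _group_slices([len(a) for a in arrays])
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_w = n_total - k
    means = np.array([a.mean() for a in arrays])
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    s2 = ssw / df_w

    out: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(arrays[i]), len(arrays[j])
            se = np.sqrt(s2 / 2.0 * (1.0 / ni + 1.0 / nj))
            diff = abs(means[i] - means[j])
            if se == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = diff / se
                p = float(stats.studentized_range.sf(q, k, df_w))
            out[(labels[i], labels[j])] = p
            out[(labels[j], labels[i])] = p
    return out


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(matrix: ExpressionMatrix,
                pairing: tuple[str, str]) -> pd.DataFrame:
    """Linear fold change condition1/condition2 per entity, with direction.

    ``fc = 2**(mean log2 of condition1 - mean log2 of condition2)``; direction
    is 'up' when fc > 1 and on exact ties (fc == 1), else 'down'.
    """
    g1, g2 = pairing
    for g in pairing:
        if not matrix.design.samples_in(g):
            raise ValueError(f"empty group {g!r}")
    m1 = matrix.group_columns(g1).mean(axis=1)
    m2 = matrix.group_columns(g2).mean(axis=1)
    fc = np.exp2(m1 - m2)
    direction = np.where(fc >= 1.0, "up", "down")
    return pd.DataFrame({"fc": fc, "direction": direction}, index=matrix.data.index)


# ---------------------------------------------------------------------------
# entity lists
# ---------------------------------------------------------------------------

@dataclass
class EntityList:
    """Significant entities for one group pairing at one alpha/fold threshold."""

    pairing: tuple[str, str]
    alpha: float
    fc_threshold: float
    members: pd.DataFrame  # entity_id, gene_name, p, q, tukey_p, fc, direction

    @property
    def n_up(self) -> int:
        return int((self.members["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.members["direction"] == "down").sum())

    @property
    def ids(self) -> set[str]:
        return set(self.members["entity_id"])

    def __len__(self) -> int:
        return len(self.members)

    def write(self, path) -> None:
        self.members.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class DEResult:
    """Entity-level statistics plus per-pairing significant lists."""

    table: pd.DataFrame            # entity_id-indexed: gene_name, F, p, q
    tukey: pd.DataFrame            # entity x pairing Tukey p (NaN if not tested)
    fc: pd.DataFrame               # entity x pairing linear fold change
    direction: pd.DataFrame        # entity x pairing up/down
    lists: dict[tuple[str, str], EntityList]
    alpha: float
    fc_threshold: float


def significant_entities(
    matrix: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC,
    bh_on: str = "omnibus",
) -> DEResult:
    """Build per-pairing significant entity lists from a preprocessed matrix."""
    if bh_on not in ("omnibus", "pairwise"):
        raise ValueError(f"bh_on must be 'omnibus' or 'pairwise', got {bh_on!r}")
    design = matrix.design
    groups = list(design.groups)
    cols = [design.samples_in(g) for g in groups]
    values = matrix.data[[s for c in cols for s in c]].to_numpy(float)
    slices = _group_slices([len(c) for c in cols])

    f, p = _anova_rows(values, slices)
    q = bh_adjust(p)
    idx = matrix.data.index
    table = pd.DataFrame(
        {"gene_name": matrix.gene_names.reindex(idx), "F": f, "p": p, "q": q},
        index=idx,
    )

    pairings = [pr for pr in PAIRINGS if pr[0] in groups and pr[1] in groups]
    pair_cols = [_pair_key(*pr) for pr in pairings]
    tukey = pd.DataFrame(np.nan, index=idx, columns=pair_cols)
    tested = q <= alpha if bh_on == "omnibus" else np.ones(len(idx), bool)
    for row in np.flatnonzero(tested):
        by_group = {g: values[row, sl] for g, sl in zip(groups, slices)}
        pp = tukey_pairwise(by_group)
        for pr, col in zip(pairings, pair_cols):
            tukey.iloc[row, tukey.columns.get_loc(col)] = pp[pr]

    fc = pd.DataFrame(index=idx, columns=pair_cols, dtype=float)
    direction = pd.DataFrame(index=idx, columns=pair_cols, dtype=object)
    for pr, col in zip(pairings, pair_cols):
        fd = fold_change(matrix, pr)
        fc[col] = fd["fc"]
        direction[col] = fd["direction"]

    lists: dict[tuple[str, str], EntityList] = {}
    for pr, col in zip(pairings, pair_cols):
        if bh_on == "omnibus":
            sig = (q <= alpha) & (tukey[col].to_numpy() <= alpha)
        else:
            qp = np.full(len(idx), np.nan)
            finite = np.isfinite(tukey[col].to_numpy(float))
            qp[finite] = bh_adjust(tukey[col].to_numpy(float)[finite])
            sig = qp <= alpha
        effect = np.maximum(fc[col].to_numpy(), 1.0 / fc[col].to_numpy())
        keep = sig & (effect >= fc_threshold)
        members = pd.DataFrame(
            {
                "entity_id": idx[keep],
                "gene_name": matrix.gene_names.reindex(idx[keep]).to_numpy(),
                "p": p[keep],
                "q": q[keep],
                "tukey_p": tukey[col].to_numpy()[keep],
                "fc": fc[col].to_numpy()[keep],
                "direction": direction[col].to_numpy()[keep],
            }
        )
        lists[pr] = EntityList(pairing=pr, alpha=alpha, fc_threshold=fc_threshold,
                               members=members)
    return DEResult(table=table, tukey=tukey, fc=fc, direction=direction,
                    lists=lists, alpha=alpha, fc_threshold=fc_threshold)


def derive_lists(de: DEResult, alpha: float,
                 fc_threshold: float) -> dict[tuple[str, str], EntityList]:
    """Rebuild entity lists at a stricter alpha or different fold threshold.

    Reuses the stored omnibus/Tukey statistics of ``de`` (computed with the
    BH-on-omnibus composition), so ``alpha`` must not exceed the alpha the
    result was computed at (Tukey p-values exist only for entities passing BH
    there).
    """
    if alpha > de.alpha:
        raise ValueError(
            f"alpha {alpha} exceeds the alpha the DE result was computed at "
            f"({de.alpha}); rerun significant_entities"
        )
    idx = de.table.index
    q = de.table["q"].to_numpy()
    p = de.table["p"].to_numpy()
    lists: dict[tuple[str, str], EntityList] = {}
    for col in de.tukey.columns:
        pr = tuple(col.split("_vs_"))
        tp = de.tukey[col].to_numpy(float)
        with np.errstate(invalid="ignore"):
            sig = (q <= alpha) & (tp <= alpha)
        fc_col = de.fc[col].to_numpy(float)
        effect = np.maximum(fc_col, 1.0 / fc_col)
        keep = sig & (effect >= fc_threshold)
        members = pd.DataFrame(
            {
                "entity_id": idx[keep],
                "gene_name": de.table["gene_name"].to_numpy()[keep],
                "p": p[keep],
                "q": q[keep],
                "tukey_p": tp[keep],
                "fc": fc_col[keep],
                "direction": de.direction[col].to_numpy()[keep],
            }
        )
        lists[pr] = EntityList(pairing=pr, alpha=alpha, fc_threshold=fc_threshold,
                               members=members)
    return lists


def collapse_replicates(entity_list: EntityList) -> EntityList:
    """Keep only the first probe (in array order) among same-named members."""
    members = entity_list.members.drop_duplicates(subset="gene_name", keep="first")
    return EntityList(
        pairing=entity_list.pairing,
        alpha=entity_list.alpha,
        fc_threshold=entity_list.fc_threshold,
        members=members.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

def venn_partition(lists: dict[str, set | EntityList]) -> dict[tuple[str, ...], set]:
    """Exact set-algebra partition of 2 or 3 entity lists.

    Returns every non-trivial region keyed by the tuple of list names whose
    members belong to that region exclusively (3 regions for 2 lists, 7 for
    3 lists); region sets are disjoint and cover the union.
    """
    if len(lists) not in (2, 3):
        raise ValueError(f"venn_partition takes 2 or 3 lists, got {len(lists)}")
    sets = {name: (v.ids if isinstance(v, EntityList) else set(v))
            for name, v in lists.items()}
    names = list(sets)
    out: dict[tuple[str, ...], set] = {}
    from itertools import combinations
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            region = set.intersection(*(sets[n] for n in combo))
            for other in names:
                if other not in combo:
                    region -= sets[other]
            out[combo] = region
    return out


def venn_counts(lists: dict[str, set | EntityList]) -> dict[tuple[str, ...], int]:
    return {k: len(v) for k, v in venn_partition(lists).items()}
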