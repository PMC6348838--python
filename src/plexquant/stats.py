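"""Compartment and group comparisons.

The primary comparison is classical one-way fixed-effects ANOVA across
compartments (or disease groups), with significance tiers attached the way
immunohistochemistry panels report them: * for p ≤ 0.05, ** for p ≤ 0.001,
*** for p ≤ 0.0001, n.s. otherwise.  Comparisons operate on per-cell
intensity values within groups when a single tissue is analysed, and on
per-patient RE values when multiple patients are present.

Pairwise Welch t-tests with Holm adjustment are provided as an explicitly
labelled extension (off by default) for post-hoc compartment contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import PlexquantError

#: Significance tiers, checked in order (inclusive thresholds).
_STAR_TIERS = (
    (0.0001, "***"),
    (0.001, "**"),
    (0.05, "*"),
)


@dataclass(frozen=True)
class GroupComparison:
    """One ANOVA result across a set of labelled groups."""

    grouping: tuple[str, ...]
    cell_type: str
    marker: str
    F_stat: float
    p_value: float
    n_per_group: tuple[int, ...]
    stars: str


def one_way_anova(groups: dict[str, np.ndarray] | list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    Returns the F statistic from the between/within sum-of-squares
    decomposition and the upper-tail p-value from the F distribution with
    (k−1, N−k) degrees of freedom.  Requires ≥2 groups with ≥2 observations
    each.
    """
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    k = len(arrays)
    if k < 2:
        raise PlexquantError(f"ANOVA requires at least 2 groups, got {k}")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise PlexquantError(
                f"ANOVA group {i} has {a.size} observation(s); at least 2 required "
                "(within-group degrees of freedom would vanish)"
            )
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        # All groups internally constant: F is 0 when means agree, infinite
        # otherwise (p -> 0); ANOVA is degenerate but the limits are clear.
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p_value = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p_value


def significance_stars(p: float) -> str:
    """Map a p-value to its panel tier: ``***`` (p ≤ 0.0001), ``**``
    (p ≤ 0.001), ``*`` (p ≤ 0.05), else ``n.s.``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    for cut, stars in _STAR_TIERS:
        if p <= cut:
            return stars
    return "n.s."


def compare_groups(
    values: pd.DataFrame,
    value_col: str,
    group_col: str,
    cell_type: str = "",
    marker: str = "",
) -> GroupComparison:
    """Run one-way ANOVA of ``value_col`` across the labels in ``group_col``."""
    groups = {
        str(label): grp[value_col].to_numpy(dtype=float)
        for label, grp in values.groupby(group_col, sort=True)
    }
    f_stat, p = one_way_anova(groups)
    return GroupComparison(
        grouping=tuple(groups),
        cell_type=cell_type,
        marker=marker,
        F_stat=f_stat,
        p_value=p,
        n_per_group=tuple(len(v) for v in groups.values()),
        stars=significance_stars(p),
    )


def compare_compartments(
    cells: pd.DataFrame,
    pheno: pd.DataFrame,
    cell_type: str,
    marker: str,
    tissue_role: str = "test",
) -> GroupComparison:
    """ANOVA of per-cell raw ``marker`` intensity across compartments for one
    cell type within the test tissue(s) of a single slide."""
    merged = cells.merge(pheno[["cell_id", "cell_type"]], on="cell_id")
    sub = merged.loc[(merged["tissue_role"] == tissue_role) & (merged["cell_type"] == cell_type)]
    if sub.empty:
        raise PlexquantError(f"no {cell_type!r} cells in {tissue_role!r} tissue")
    return compare_groups(sub, marker, "compartment", cell_type=cell_type, marker=marker)


def pairwise_welch_holm(
    values: pd.DataFrame, value_col: str, group_col: str
) -> pd.DataFrame:
    """Post-hoc extension: pairwise Welch t-tests with Holm adjustment.

    Not part of the core comparison (the primary analysis reports only the
    omnibus ANOVA); provided for users who need compartment-pair contrasts.
    """
    groups = {
        str(label): grp[value_col].to_numpy(dtype=float)
        for label, grp in values.groupby(group_col, sort=True)
    }
    rows = []
    for a, b in combinations(sorted(groups), 2):
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t_stat": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
        out["stars"] = out["p_holm"].map(significance_stars)
    return out
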