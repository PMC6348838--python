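"""Threshold calibration and cell gating.

Positivity cutoffs follow the negative-control rule: for each marker, the
raw fluorescence of 50-200 cells expected to lack the marker is measured,
and the brightest of those "false positive" readings becomes the cutoff.
A cell is called positive only when its intensity strictly exceeds the
cutoff.  Cell types are then assigned from the boolean marker calls by a
fixed precedence (regulatory T cells first, then cytotoxic/helper/other T
cells, B, NK, dendritic cells, macrophages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, SchemaError
from .panel import (
    CELL_TYPE_PRECEDENCE,
    MarkerPanel,
    DEFAULT_PANEL,
    OTHER_CELL_TYPE,
)

#: Calibration window: number of negative-control cells per marker.
DEFAULT_NEGATIVE_WINDOW = (50, 200)

#: Top-quantile used for the provisional lineage gates that bootstrap
#: calibration before any threshold exists (a cell in the top decile of raw
#: CD20 is a B cell with near certainty in lymphoid tissue).
_PROVISIONAL_QUANTILE = 0.90


@dataclass(frozen=True)
class NegativeControlRule:
    """How to find cells expected to lack a marker.

    ``gate_marker`` names a lineage marker whose positive cells are known to
    lack the target marker (e.g. CD20+ B cells lack TIGIT and PD-1).  If a
    calibrated threshold for ``gate_marker`` is available the gate is
    threshold-based; otherwise cells in the top decile of the gate marker's
    raw intensity are used as a provisional gate.  ``exclude_markers`` lists
    markers whose positive cells are additionally removed from the pool
    (applied when those markers have calibrated thresholds): a negative
    control for the checkpoints must be CD20+ *and* CD3-, because a rare
    spuriously CD20-bright T cell would carry genuine checkpoint signal and
    corrupt the maximum-based cutoff.
    """

    gate_marker: str
    description: str = ""
    exclude_markers: tuple[str, ...] = ()


def default_negative_rules(panel: MarkerPanel = DEFAULT_PANEL) -> dict[str, NegativeControlRule]:
    """Default negative-control rules: checkpoint and T/NK/myeloid markers
    calibrate on B cells (CD20 gate, CD3-excluded for the checkpoints);
    CD20 itself calibrates on T cells."""
    rules = {}
    for marker in panel.markers:
        if marker == "CD20":
            rules[marker] = NegativeControlRule("CD3", "CD3-gated T cells (lack CD20)")
        elif marker in panel.checkpoint_markers:
            rules[marker] = NegativeControlRule(
                "CD20", "CD20-gated CD3-negative B cells (lack this marker)", ("CD3",)
            )
        else:
            rules[marker] = NegativeControlRule("CD20", "CD20-gated B cells (lack this marker)")
    return rules


@dataclass
class ThresholdSet:
    """Per-marker positivity cutoffs with calibration provenance."""

    cutoffs: dict[str, float] = field(default_factory=dict)
    n_negative_cells: dict[str, int] = field(default_factory=dict)
    negative_selector: dict[str, str] = field(default_factory=dict)

    def covers(self, panel: MarkerPanel) -> bool:
        return all(m in self.cutoffs for m in panel.markers)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "cutoffs": {m: float(v) for m, v in self.cutoffs.items()},
                    "n_negative_cells": {m: int(v) for m, v in self.n_negative_cells.items()},
                    "negative_selector": dict(self.negative_selector),
                },
                sort_keys=True,
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdSet":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            cutoffs=d["cutoffs"],
            n_negative_cells=d.get("n_negative_cells", {}),
            negative_selector=d.get("negative_selector", {}),
        )


def calibrate_threshold(
    cells: pd.DataFrame,
    marker: str,
    negative_cell_ids: set[str] | list[str],
    window: tuple[int, int] = DEFAULT_NEGATIVE_WINDOW,
) -> float:
    """Cutoff = maximum intensity of ``marker`` over the negative-control cells.

    The negative set must contain between ``window[0]`` and ``window[1]``
    cells (default 50-200), all present in the table.
    """
    if marker not in cells.columns:
        raise SchemaError(f"marker {marker!r} not present in cell table")
    ids = set(negative_cell_ids)
    lo, hi = window
    if not (lo <= len(ids) <= hi):
        raise CalibrationError(
            f"negative-control set for {marker!r} has {len(ids)} cells; "
            f"required window is [{lo}, {hi}]"
        )
    mask = cells["cell_id"].isin(ids)
    if int(mask.sum()) != len(ids):
        raise CalibrationError(
            f"{len(ids) - int(mask.sum())} negative-control ids for {marker!r} "
            "are missing from the cell table"
        )
    return float(cells.loc[mask, marker].max())


def select_negative_controls(
    cells: pd.DataFrame,
    marker: str,
    rule: NegativeControlRule,
    max_n: int = DEFAULT_NEGATIVE_WINDOW[1],
    seed: int = 0,
    thresholds: ThresholdSet | None = None,
    min_n: int = DEFAULT_NEGATIVE_WINDOW[0],
) -> list[str]:
    """Reproducibly sample negative-control cells for ``marker``.

    Eligible cells are those passing the rule's lineage gate: above the gate
    marker's calibrated cutoff when available, otherwise in the top decile
    of its raw intensity (provisional gate).  Between ``min_n`` and
    ``max_n`` ids are drawn uniformly without replacement under ``seed``.
    """
    gm = rule.gate_marker
    if gm not in cells.columns:
        raise SchemaError(f"gate marker {gm!r} not present in cell table")
    if thresholds is not None and gm in thresholds.cutoffs:
        mask = cells[gm] > thresholds.cutoffs[gm]
    else:
        mask = cells[gm] > cells[gm].quantile(_PROVISIONAL_QUANTILE)
    if thresholds is not None:
        for em in rule.exclude_markers:
            if em in thresholds.cutoffs and em in cells.columns:
                mask &= ~(cells[em] > thresholds.cutoffs[em])
    ids = cells.loc[mask, "cell_id"].to_numpy()
    if ids.size < min_n:
        raise CalibrationError(
            f"only {ids.size} eligible negative-control cells for {marker!r} "
            f"(gate {gm!r}); at least {min_n} required — use a larger input region"
        )
    rng = np.random.default_rng(seed)
    if ids.size > max_n:
        ids = rng.choice(ids, size=max_n, replace=False)
    return sorted(ids.tolist())


def calibrate_panel(
    cells: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    rules: dict[str, NegativeControlRule] | None = None,
    seed: int = 0,
    max_n: int = DEFAULT_NEGATIVE_WINDOW[1],
    window: tuple[int, int] = DEFAULT_NEGATIVE_WINDOW,
) -> ThresholdSet:
    """Calibrate every panel marker in two passes.

    Lineage markers are calibrated first from provisional (top-decile)
    gates; checkpoint markers then use the calibrated lineage gates (e.g.
    TIGIT and PD-1 negatives are drawn from threshold-gated CD20+ B cells).
    """
    rules = rules or default_negative_rules(panel)
    thresholds = ThresholdSet()
    for pass_markers, use_thresholds in (
        (panel.lineage_markers, False),
        (panel.checkpoint_markers, True),
    ):
        for marker in pass_markers:
            rule = rules[marker]
            ids = select_negative_controls(
                cells,
                marker,
                rule,
                max_n=max_n,
                seed=seed,
                thresholds=thresholds if use_thresholds else None,
                min_n=window[0],
            )
            thresholds.cutoffs[marker] = calibrate_threshold(cells, marker, ids, window=window)
            thresholds.n_negative_cells[marker] = len(ids)
            thresholds.negative_selector[marker] = rule.description or f"{rule.gate_marker}-gated"
    return thresholds


_CHECKPOINT_STATES = {
    (True, True): "TIGIT+PD1+",
    (True, False): "TIGIT+PD1-",
    (False, True): "TIGIT-PD1+",
    (False, False): "TIGIT-PD1-",
}


def call_positivity(
    cells: pd.DataFrame,
    thresholds: ThresholdSet,
    panel: MarkerPanel = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Per-cell boolean marker calls; positive iff intensity > cutoff (strict).

    A cell exactly at the cutoff is negative: the calibration rule defines
    the cutoff as the brightest known-negative cell, so equalling it is not
    evidence of expression.
    """
    if not thresholds.covers(panel):
        missing = [m for m in panel.markers if m not in thresholds.cutoffs]
        raise SchemaError(f"thresholds missing for markers: {missing}")
    pheno = cells[["cell_id"]].copy()
    for marker in panel.markers:
        pheno[f"{marker}_pos"] = cells[marker].to_numpy() > thresholds.cutoffs[marker]
    pheno = assign_cell_type(pheno)
    if {"TIGIT", "PD-1"} <= set(panel.markers):
        t = pheno["TIGIT_pos"].to_numpy()
        p = pheno["PD-1_pos"].to_numpy()
        states = np.where(
            t & p, "TIGIT+PD1+", np.where(t, "TIGIT+PD1-", np.where(p, "TIGIT-PD1+", "TIGIT-PD1-"))
        )
        pheno["checkpoint_state"] = states
    return pheno


def assign_cell_type(pheno: pd.DataFrame) -> pd.DataFrame:
    """Fill ``cell_type`` from boolean marker calls by fixed precedence:
    FOXP3 → CD8 → CD4 → CD3 → CD20 → CD56 → CD11c → CD68 → other."""
    pheno = pheno.copy()
    cell_type = np.full(len(pheno), OTHER_CELL_TYPE, dtype=object)
    assigned = np.zeros(len(pheno), dtype=bool)
    for marker, label in CELL_TYPE_PRECEDENCE:
        col = f"{marker}_pos"
        if col not in pheno.columns:
            continue
        hit = pheno[col].to_numpy(dtype=bool) & ~assigned
        cell_type[hit] = label
        assigned |= hit
    pheno["cell_type"] = cell_type
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in df.columns:
        if col.endswith("_pos"):
            df[col] = df[col].astype(bool)
    return df
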