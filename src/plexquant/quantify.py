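"""Headline quantities: relative expression, ratios, coexpression, density.

Relative expression (RE) normalizes the mean raw intensity of a test cell
population to reference tonsil germinal-centre cells carried on the same
slide (reference mean = 100%).  The TIGIT:PD-1 ratio is the ratio of the
two markers' RE values within one population.  Densities convert cell
counts on circular tissue spots to cells per mm² (or per 0.1 mm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, InsufficientCellsError, UndefinedReferenceError
from .panel import CHECKPOINT_MARKERS, SUMMARY_CELL_TYPES

#: Populations with fewer cells than this are flagged low-n in summaries.
DEFAULT_MIN_N = 20


# ---------------------------------------------------------------------------
# Relative expression and ratios
# ---------------------------------------------------------------------------

def relative_expression(
    test_cells: pd.DataFrame, reference_cells: pd.DataFrame, marker: str
) -> float:
    """RE = 100 · mean(test intensities) / mean(reference intensities).

    Both populations must be non-empty and the reference mean must be
    positive (a zero reference mean would make the percentage undefined).
    """
    if len(test_cells) == 0:
        raise InsufficientCellsError(f"empty test cell set for marker {marker!r}")
    if len(reference_cells) == 0:
        raise UndefinedReferenceError(f"empty reference cell set for marker {marker!r}")
    ref_mean = float(reference_cells[marker].mean())
    if ref_mean <= 0.0:
        raise UndefinedReferenceError(
            f"reference mean intensity for {marker!r} is {ref_mean}; RE undefined"
        )
    # ratio first: a population measured against itself is exactly 100.
    return 100.0 * (float(test_cells[marker].mean()) / ref_mean)


def tigit_pd1_ratio(re_tigit: float, re_pd1: float) -> float:
    """TIGIT:PD-1 expression ratio = RE[TIGIT] / RE[PD-1]."""
    if re_pd1 <= 0.0:
        raise UndefinedReferenceError(f"RE[PD-1] = {re_pd1}; TIGIT:PD-1 ratio undefined")
    return re_tigit / re_pd1


# ---------------------------------------------------------------------------
# Coexpression and positivity fractions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoexpressionResult:
    """Conditional TIGIT/PD-1 coexpression on a scoped cell set.

    Fractions are ``None`` (undefined, not zero) when the conditioning
    population is empty.
    """

    frac_tigit_pos_that_are_pd1_pos: float | None
    frac_pd1_pos_that_are_tigit_pos: float | None
    n_tigit_pos: int
    n_pd1_pos: int
    n_double_pos: int


def coexpression_fractions(pheno: pd.DataFrame, scope: pd.Series | None = None) -> CoexpressionResult:
    """Compute P(PD-1+ | TIGIT+) and P(TIGIT+ | PD-1+) on the scoped cells."""
    sub = pheno if scope is None else pheno.loc[np.asarray(scope, dtype=bool)]
    t = sub["TIGIT_pos"].to_numpy(dtype=bool)
    p = sub["PD-1_pos"].to_numpy(dtype=bool)
    n_t, n_p, n_tp = int(t.sum()), int(p.sum()), int((t & p).sum())
    return CoexpressionResult(
        frac_tigit_pos_that_are_pd1_pos=(n_tp / n_t) if n_t else None,
        frac_pd1_pos_that_are_tigit_pos=(n_tp / n_p) if n_p else None,
        n_tigit_pos=n_t,
        n_pd1_pos=n_p,
        n_double_pos=n_tp,
    )


def positivity_fraction(pheno: pd.DataFrame, cell_type: str, marker: str) -> float | None:
    """Fraction of cells of ``cell_type`` called positive for ``marker``;
    ``None`` when no cell of the type is present."""
    sub = pheno.loc[pheno["cell_type"] == cell_type, f"{marker}_pos"]
    if len(sub) == 0:
        return None
    return float(sub.mean())


def t_subtype_mask(pheno: pd.DataFrame, subtype: str) -> pd.Series:
    """Boolean mask for a gated T-cell subtype population.

    A CD4+/CD8+/FOXP3+ *T cell* must carry the CD3 call in addition to the
    subtype label: in compartments where another lineage vastly outnumbers
    the subtype (B-cell-rich germinal centres), the occasional spurious
    subtype-marker call on a non-T cell would otherwise dilute the
    population, because the labelling precedence alone does not require CD3.
    """
    return (pheno["cell_type"] == subtype) & pheno["CD3_pos"]


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotGeometry:
    """Circular tissue-spot geometry; area derived from the diameter."""

    diameter_mm: float
    area_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise GeometryError(f"spot diameter must be positive, got {self.diameter_mm}")
        object.__setattr__(self, "area_mm2", math.pi * (self.diameter_mm / 2.0) ** 2)


@dataclass(frozen=True)
class DensityRecord:
    tissue_id: str
    phenotype: str
    count: int
    area_mm2: float
    density: float


def density(count: int, geometry: SpotGeometry) -> float:
    """Cells per mm² on a circular spot: count / (π·(d/2)²)."""
    if count < 0:
        raise ValueError("cell count cannot be negative")
    return count / geometry.area_mm2


def density_per_0p1mm2(count: int, region_area_mm2: float) -> float:
    """Cells per 0.1 mm² in an arbitrary region: count · 0.1 / area."""
    if region_area_mm2 <= 0:
        raise GeometryError(f"region area must be positive, got {region_area_mm2}")
    if count < 0:
        raise ValueError("cell count cannot be negative")
    return count * 0.1 / region_area_mm2


def spot_density_table(
    cells: pd.DataFrame,
    pheno: pd.DataFrame,
    geometry: SpotGeometry,
    phenotype_masks: dict[str, pd.Series],
) -> pd.DataFrame:
    """Per-tissue density records for named phenotype selections
    (e.g. ``{"TIGIT+": pheno["TIGIT_pos"], "CD8+TIGIT+": ...}``)."""
    merged = cells[["cell_id", "tissue_id"]].merge(pheno, on="cell_id")
    rows = []
    for tissue_id, grp in merged.groupby("tissue_id", sort=True):
        for name, mask in phenotype_masks.items():
            count = int(mask.loc[grp.index].sum()) if hasattr(mask, "loc") else int(
                np.asarray(mask)[grp.index].sum()
            )
            rows.append(
                {
                    "tissue_id": tissue_id,
                    "phenotype": name,
                    "count": count,
                    "area_mm2": geometry.area_mm2,
                    "density": density(count, geometry),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Compartment summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSpec:
    """Which cells define 100% expression: a tissue and compartment
    (default: the reference tonsil's germinal-centre periphery)."""

    tissue_id: str | None = None
    tissue_role: str = "reference"
    compartment: str = "Gcp"


def _reference_mask(cells: pd.DataFrame, ref: ReferenceSpec) -> pd.Series:
    if ref.tissue_id is not None:
        mask = cells["tissue_id"] == ref.tissue_id
    else:
        mask = cells["tissue_role"] == ref.tissue_role
    return mask & (cells["compartment"] == ref.compartment)


def summarize_compartments(
    cells: pd.DataFrame,
    pheno: pd.DataFrame,
    reference_spec: ReferenceSpec = ReferenceSpec(),
    cell_types: tuple[str, ...] = SUMMARY_CELL_TYPES,
    markers: tuple[str, ...] = CHECKPOINT_MARKERS,
    min_n: int = DEFAULT_MIN_N,
    pooled_reference: bool = False,
) -> pd.DataFrame:
    """One row per (tissue, compartment, cell type) with n, mean raw
    checkpoint intensities, RE against the type-matched reference
    population, and the TIGIT:PD-1 ratio.

    By default the reference population is type-matched (test CD8 T cells
    are normalized to reference CD8 T cells); ``pooled_reference=True``
    normalizes every type to all reference-compartment cells instead.
    Rows with fewer than ``min_n`` cells are flagged ``low_n``.
    """
    merged = cells.merge(pheno[["cell_id", "cell_type"]], on="cell_id", how="left")
    ref_mask = _reference_mask(merged, reference_spec)
    if not ref_mask.any():
        raise UndefinedReferenceError(
            f"no reference cells found (role={reference_spec.tissue_role!r}, "
            f"tissue={reference_spec.tissue_id!r}, compartment={reference_spec.compartment!r})"
        )
    ref_cells = merged.loc[ref_mask]

    rows = []
    for (tissue_id, compartment), grp in merged.groupby(["tissue_id", "compartment"], sort=True):
        for ct in cell_types:
            sub = grp.loc[grp["cell_type"] == ct]
            if len(sub) == 0:
                continue
            ref_sub = ref_cells if pooled_reference else ref_cells.loc[ref_cells["cell_type"] == ct]
            row: dict = {
                "tissue_id": tissue_id,
                "compartment": compartment,
                "cell_type": ct,
                "n_cells": len(sub),
                "low_n": len(sub) < min_n,
            }
            re_vals = {}
            for marker in markers:
                row[f"mean_raw_{marker}"] = float(sub[marker].mean())
                re_vals[marker] = relative_expression(sub, ref_sub, marker)
                row[f"RE_{marker}"] = re_vals[marker]
            if {"TIGIT", "PD-1"} <= set(markers):
                row["ratio_tigit_pd1"] = tigit_pd1_ratio(re_vals["TIGIT"], re_vals["PD-1"])
            rows.append(row)
    return pd.DataFrame(rows)
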