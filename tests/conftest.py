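from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from plexquant import (
    CompartmentSpec,
    CoPositivity,
    GeneratorConfig,
    IntensityMixture,
    ThresholdSet,
    calibrate_panel,
    call_positivity,
    generate_cells,
    make_preset,
)
from plexquant.panel import CELL_TYPES, DEFAULT_PANEL


def small_config(
    seed: int = 7,
    n_cells: int = 1000,
    tigit_fraction: float = 0.5,
    copos: CoPositivity | None = None,
    reference: bool = False,
) -> GeneratorConfig:
    """A compact two-cell-type, one-compartment cohort for fast unit tests."""
    mixtures = {}
    for ct in CELL_TYPES:
        for m in DEFAULT_PANEL.lineage_markers:
            defining = {
                "CD3_T": ("CD3",), "CD4_T": ("CD3", "CD4"), "CD8_T": ("CD3", "CD8"),
                "FOXP3_Treg": ("CD3", "CD4", "FOXP3"), "CD20_B": ("CD20",),
                "CD56_NK": ("CD56",), "CD11c_DC": ("CD11c",), "CD68_Mac": ("CD68",),
                "other": (),
            }[ct]
            mixtures[(ct, m)] = IntensityMixture(0.0, 0.35, 2.5, 0.35, 1.0 if m in defining else 0.0)
        mixtures[(ct, "TIGIT")] = IntensityMixture(
            0.0, 0.4, 2.2, 0.35, tigit_fraction if ct in ("CD3_T", "CD4_T", "CD8_T") else 0.0
        )
        mixtures[(ct, "PD-1")] = IntensityMixture(0.0, 0.4, 2.0, 0.35, 0.0)
    comp = CompartmentSpec(
        name="zone_a",
        n_cells=n_cells,
        cell_type_proportions={"CD3_T": 0.4, "CD20_B": 0.4, "other": 0.2},
    )
    ref = (
        CompartmentSpec(
            name="Gcp",
            n_cells=max(200, n_cells // 2),
            cell_type_proportions={"CD3_T": 0.4, "CD20_B": 0.4, "other": 0.2},
        ),
    )
    return GeneratorConfig(
        panel=DEFAULT_PANEL,
        compartments=(comp,),
        mixtures=mixtures,
        copositivity={ct: copos or CoPositivity(0.7, 0.9) for ct in CELL_TYPES},
        spot_diameter_mm=1.0,
        seed=seed,
        reference_included=reference,
        reference_compartments=ref if reference else (),
        name="unit_test",
    )


@dataclass(frozen=True)
class TonsilRun:
    """One calibrated, gated tonsil-preset run shared across tests."""

    cells: pd.DataFrame
    truth: pd.DataFrame
    thresholds: ThresholdSet
    pheno: pd.DataFrame
    merged: pd.DataFrame  # cells ⋈ pheno ⋈ truth
    seed: int


def run_tonsil(seed: int) -> TonsilRun:
    cfg = make_preset("tonsil", seed=seed)
    sim = generate_cells(cfg)
    thresholds = calibrate_panel(sim.cells, seed=seed)
    pheno = call_positivity(sim.cells, thresholds)
    merged = sim.cells.merge(pheno, on="cell_id").merge(sim.truth, on="cell_id")
    return TonsilRun(
        cells=sim.cells,
        truth=sim.truth,
        thresholds=thresholds,
        pheno=pheno,
        merged=merged,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tonsil_run() -> TonsilRun:
    return run_tonsil(seed=1)
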