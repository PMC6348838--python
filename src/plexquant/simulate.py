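"""Synthetic per-cell intensity tables.

Emulates the measurement output of a scanned multiplex immunofluorescence
slide: one row per segmented cell carrying raw fluorescence intensities for
every panel marker.  Each cell type draws each marker from a two-component
lognormal mixture (dim background vs. bright expressing population); the two
checkpoint receptors are drawn jointly so that configured conditional
co-positivities P(PD-1+|TIGIT+) and P(TIGIT+|PD-1+) hold; compartment
gradients brighten the expressing population compartment by compartment.

Ground truth (the simulated cell type and checkpoint positivity of every
cell) is returned as a separate sidecar table so the analysis pipeline can
never consume it by accident.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GeneratorConfig, CompartmentSpec
from .errors import ConfigurationError

TABLE_ID_COLUMNS = ("cell_id", "tissue_id", "tissue_role", "compartment", "x_um", "y_um")


@dataclass(frozen=True)
class SimulationResult:
    """Cell table plus its ground-truth sidecar and resolved configuration."""

    cells: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _disc_positions(rng: np.random.Generator, n: int, diameter_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform positions (µm) in a disc centred at the origin."""
    radius_um = diameter_mm / 2.0 * 1000.0
    r = radius_um * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    return r * np.cos(theta), r * np.sin(theta)


def _draw_checkpoint_indicators(
    rng: np.random.Generator,
    n: int,
    config: GeneratorConfig,
    cell_type: str,
    comp: CompartmentSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint TIGIT/PD-1 positivity from the resolved 2x2 table."""
    p_tigit = config.tigit_fraction(cell_type, comp)
    table = config.copositivity_for(cell_type, comp.name).joint_table(p_tigit, cell_type=cell_type)
    u = rng.random(n)
    # Cumulative cut-points over (T+P+, T+P-, T-P+, T-P-).
    c_pp = table["pp"]
    c_pn = c_pp + table["pn"]
    c_np = c_pn + table["np"]
    tigit = u < c_pn
    pd1 = (u < c_pp) | ((u >= c_pn) & (u < c_np))
    return tigit, pd1


def _draw_marker_intensity(
    rng: np.random.Generator,
    positive: np.ndarray,
    config: GeneratorConfig,
    cell_type: str,
    marker: str,
    gradient_factor: float,
) -> np.ndarray:
    mix = config.mixture_for(cell_type, marker)
    n = positive.size
    out = np.empty(n)
    n_pos = int(positive.sum())
    if n_pos:
        out[positive] = rng.lognormal(
            mix.pos_log_mean + np.log(gradient_factor), mix.pos_log_sd, n_pos
        )
    if n_pos < n:
        out[~positive] = rng.lognormal(mix.neg_log_mean, mix.neg_log_sd, n - n_pos)
    return out


def generate_cells(config: GeneratorConfig) -> SimulationResult:
    """Generate the synthetic cohort described by ``config``.

    Returns one row per cell.  Per compartment, cell-type counts are
    multinomial with the configured proportions; marker intensities follow
    the cell type's mixtures (with compartment checkpoint gradients);
    TIGIT/PD-1 positivity follows the configured conditional co-positivities;
    positions are uniform within the spot disc.  A fixed ``config.seed``
    yields a byte-identical serialized table.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    cell_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    counter = 0

    tissues: list[tuple[str, str, tuple[CompartmentSpec, ...]]] = [
        (config.tissue_id, "test", config.compartments)
    ]
    if config.reference_included:
        tissues.append((config.reference_tissue_id, "reference", config.reference_compartments))

    for tissue_id, role, compartments in tissues:
        for comp in compartments:
            cell_types = sorted(comp.cell_type_proportions)
            probs = np.array([comp.cell_type_proportions[ct] for ct in cell_types])
            counts = rng.multinomial(comp.n_cells, probs)
            for cell_type, k in zip(cell_types, counts):
                if k == 0:
                    continue
                tigit_pos, pd1_pos = _draw_checkpoint_indicators(rng, k, config, cell_type, comp)
                intensities = {}
                for marker in panel.markers:
                    if marker == "TIGIT":
                        positive = tigit_pos
                    elif marker == "PD-1":
                        positive = pd1_pos
                    else:
                        frac = comp.pos_fraction_overrides.get(
                            (cell_type, marker), config.mixture_for(cell_type, marker).pos_fraction
                        )
                        positive = rng.random(k) < frac
                    grad = comp.checkpoint_gradient.get(marker, 1.0)
                    intensities[marker] = _draw_marker_intensity(
                        rng, positive, config, cell_type, marker, grad
                    )
                x, y = _disc_positions(rng, k, config.spot_diameter_mm)
                ids = [f"{tissue_id}_c{counter + i:06d}" for i in range(k)]
                counter += k
                cell_rows.append(
                    pd.DataFrame(
                        {
                            "cell_id": ids,
                            "tissue_id": tissue_id,
                            "tissue_role": role,
                            "compartment": comp.name,
                            "x_um": x,
                            "y_um": y,
                            **intensities,
                        }
                    )
                )
                truth_rows.append(
                    pd.DataFrame(
                        {
                            "cell_id": ids,
                            "true_cell_type": cell_type,
                            "true_TIGIT_pos": tigit_pos.astype(int),
                            "true_PD-1_pos": pd1_pos.astype(int),
                        }
                    )
                )

    if not cell_rows:
        raise ConfigurationError("configuration generated zero cells")
    cells = pd.concat(cell_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return SimulationResult(cells=cells, truth=truth, config=config)
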