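"""Reading and writing the pipeline's delimited-text artifacts.

Cell tables are plain CSV with a fixed identity header
(``cell_id, tissue_id, tissue_role, compartment, x_um, y_um``) followed by
one raw-intensity column per panel marker.  Floats are written with
shortest-round-trip formatting, so write→read is exact and output is
byte-identical for identical input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .panel import MarkerPanel, DEFAULT_PANEL
from .simulate import TABLE_ID_COLUMNS

_VALID_ROLES = {"test", "reference"}


def write_cells(cells: pd.DataFrame, path: str | Path, panel: MarkerPanel = DEFAULT_PANEL) -> None:
    """Write a cell table as CSV with identity columns first, markers after."""
    cols = list(TABLE_ID_COLUMNS) + [m for m in panel.markers if m in cells.columns]
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table is missing columns: {missing}")
    cells[cols].to_csv(path, index=False)


def read_cells(
    cells_or_path: str | Path,
    panel: MarkerPanel = DEFAULT_PANEL,
    known_compartments: set[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a cell table.

    Raises :class:`SchemaError` naming the offending column or the 1-based
    data row for a missing marker column, a negative intensity, or (when
    ``known_compartments`` is given) an unrecognized compartment label.
    """
    df = pd.read_csv(cells_or_path)
    for col in TABLE_ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table is missing required column {col!r}")
    for marker in panel.markers:
        if marker not in df.columns:
            raise SchemaError(f"cell table is missing marker column {marker!r}")
    for marker in panel.markers:
        vals = pd.to_numeric(df[marker], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals) | (vals < 0))
        if bad.size:
            row = int(bad[0]) + 1
            raise SchemaError(
                f"marker {marker!r}: intensity {df[marker].iloc[bad[0]]!r} at data row {row} "
                "violates non-negativity"
            )
        df[marker] = vals.astype(float)
    bad_role = ~df["tissue_role"].isin(_VALID_ROLES)
    if bad_role.any():
        row = int(np.flatnonzero(bad_role)[0]) + 1
        raise SchemaError(f"unknown tissue_role at data row {row}")
    if known_compartments is not None:
        unknown = ~df["compartment"].isin(known_compartments)
        if unknown.any():
            row = int(np.flatnonzero(unknown)[0]) + 1
            raise SchemaError(
                f"unknown compartment {df['compartment'].iloc[row - 1]!r} at data row {row}"
            )
    if df["cell_id"].duplicated().any():
        raise SchemaError("duplicate cell_id values in cell table")
    return df


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the generator's ground-truth sidecar table."""
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
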