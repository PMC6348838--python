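"""Marker panel and cell-type vocabulary.

The default panel mirrors a ten-plex immunofluorescence experiment: eight
lineage markers identifying the major leucocyte populations of lymphoid
tissue, plus the two inhibitory checkpoint receptors TIGIT and PD-1 whose
expression the pipeline quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

DEFAULT_LINEAGE_MARKERS = ("CD3", "CD4", "CD8", "FOXP3", "CD20", "CD56", "CD11c", "CD68")
CHECKPOINT_MARKERS = ("TIGIT", "PD-1")

#: Cell-type labels, in gating-precedence order (first match wins).
#: FOXP3 identifies regulatory T cells regardless of other T-cell markers;
#: the remaining lineages are resolved in the order below.
CELL_TYPE_PRECEDENCE = (
    ("FOXP3", "FOXP3_Treg"),
    ("CD8", "CD8_T"),
    ("CD4", "CD4_T"),
    ("CD3", "CD3_T"),
    ("CD20", "CD20_B"),
    ("CD56", "CD56_NK"),
    ("CD11c", "CD11c_DC"),
    ("CD68", "CD68_Mac"),
)

OTHER_CELL_TYPE = "other"

CELL_TYPES = tuple(label for _, label in CELL_TYPE_PRECEDENCE) + (OTHER_CELL_TYPE,)

#: T-cell subtypes reported in compartment summaries.
SUMMARY_CELL_TYPES = ("CD4_T", "CD8_T", "FOXP3_Treg")

#: Lineage markers that define each cell type as positive in the generator.
#: All T-cell subtypes carry CD3; regulatory T cells additionally carry CD4.
CELL_TYPE_DEFINING_MARKERS = {
    "CD3_T": ("CD3",),
    "CD4_T": ("CD3", "CD4"),
    "CD8_T": ("CD3", "CD8"),
    "FOXP3_Treg": ("CD3", "CD4", "FOXP3"),
    "CD20_B": ("CD20",),
    "CD56_NK": ("CD56",),
    "CD11c_DC": ("CD11c",),
    "CD68_Mac": ("CD68",),
    OTHER_CELL_TYPE: (),
}


@dataclass(frozen=True)
class MarkerPanel:
    """The set of markers measured per cell.

    Parameters
    ----------
    lineage_markers
        Markers used for phenotyping (B/T/NK/dendritic/macrophage lineages).
    checkpoint_markers
        Checkpoint receptors whose expression is quantified; the default
        panel measures exactly TIGIT and PD-1.
    """

    lineage_markers: tuple[str, ...] = DEFAULT_LINEAGE_MARKERS
    checkpoint_markers: tuple[str, ...] = CHECKPOINT_MARKERS

    def __post_init__(self) -> None:
        all_markers = tuple(self.lineage_markers) + tuple(self.checkpoint_markers)
        if len(set(all_markers)) != len(all_markers):
            raise ConfigurationError("marker names must be unique across lineage and checkpoint lists")
        object.__setattr__(self, "lineage_markers", tuple(self.lineage_markers))
        object.__setattr__(self, "checkpoint_markers", tuple(self.checkpoint_markers))

    @property
    def markers(self) -> tuple[str, ...]:
        """All markers, lineage first, in panel order."""
        return tuple(self.lineage_markers) + tuple(self.checkpoint_markers)


DEFAULT_PANEL = MarkerPanel()
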