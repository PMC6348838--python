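"""Generator configuration types.

A :class:`GeneratorConfig` fully parameterizes a synthetic cohort: the marker
panel, the tissue compartments with their cell-type composition, the
per-(cell-type, marker) lognormal intensity mixtures, the TIGIT/PD-1
co-positivity structure, spot geometry and the seed.  Configurations
round-trip through YAML so every simulated table can be regenerated from its
provenance file alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .panel import MarkerPanel, DEFAULT_PANEL

_PROP_TOL = 1e-9


@dataclass(frozen=True)
class IntensityMixture:
    """Two-component lognormal intensity model for one (cell type, marker).

    Background ("negative") and expressing ("positive") cells each draw raw
    fluorescence from a lognormal; ``pos_fraction`` is the probability that a
    cell of this type truly expresses the marker.  Units are arbitrary
    scanner units; only ratios of means are meaningful downstream.
    """

    neg_log_mean: float
    neg_log_sd: float
    pos_log_mean: float
    pos_log_sd: float
    pos_fraction: float

    def __post_init__(self) -> None:
        if self.neg_log_sd <= 0 or self.pos_log_sd <= 0:
            raise ConfigurationError("mixture log-sds must be positive")
        if not (0.0 <= self.pos_fraction <= 1.0):
            raise ConfigurationError(f"pos_fraction {self.pos_fraction} outside [0, 1]")
        if self.pos_fraction > 0 and self.pos_log_mean <= self.neg_log_mean:
            raise ConfigurationError(
                "positive component must be brighter than background "
                f"(pos_log_mean {self.pos_log_mean} <= neg_log_mean {self.neg_log_mean})"
            )


@dataclass(frozen=True)
class CoPositivity:
    """Conditional co-positivity of the two checkpoint receptors.

    ``p_pd1_given_tigit`` is P(PD-1+ | TIGIT+) and ``p_tigit_given_pd1`` is
    P(TIGIT+ | PD-1+).  Together with the TIGIT marginal they determine the
    full 2x2 joint table of the two positivity indicators.
    """

    p_pd1_given_tigit: float
    p_tigit_given_pd1: float

    def __post_init__(self) -> None:
        for name in ("p_pd1_given_tigit", "p_tigit_given_pd1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} = {v} outside [0, 1]")

    def joint_table(self, p_tigit: float, cell_type: str = "?") -> dict[str, float]:
        """Resolve the 2x2 joint probability table implied by the marginal.

        Raises :class:`ConfigurationError` (naming the cell type) if the
        conditionals are jointly infeasible with the TIGIT marginal.
        """
        c1, c2 = self.p_pd1_given_tigit, self.p_tigit_given_pd1
        joint = c1 * p_tigit
        if joint == 0.0:
            p_pd1 = 0.0
        else:
            if c2 == 0.0:
                raise ConfigurationError(
                    f"cell type {cell_type!r}: P(TIGIT+|PD-1+)=0 with a nonzero joint probability"
                )
            p_pd1 = joint / c2
        if p_pd1 > 1.0 + _PROP_TOL:
            raise ConfigurationError(
                f"cell type {cell_type!r}: implied PD-1 marginal {p_pd1:.4f} exceeds 1"
            )
        p_tn_pp = p_pd1 - joint  # TIGIT- PD-1+
        if p_tn_pp > (1.0 - p_tigit) + _PROP_TOL:
            raise ConfigurationError(
                f"cell type {cell_type!r}: co-positivity conditionals inconsistent with "
                f"TIGIT marginal {p_tigit:.3f} (implied P(TIGIT-,PD-1+)={p_tn_pp:.4f} "
                f"> P(TIGIT-)={1.0 - p_tigit:.4f})"
            )
        return {
            "pp": joint,
            "pn": p_tigit - joint,
            "np": min(p_tn_pp, 1.0 - p_tigit),
            "nn": max(0.0, 1.0 - p_tigit - p_tn_pp),
            "p_pd1": min(p_pd1, 1.0),
        }


@dataclass(frozen=True)
class CompartmentSpec:
    """One pathologist-defined tissue compartment.

    ``checkpoint_gradient`` scales the positive-component median intensity of
    each checkpoint marker in this compartment (a factor of 2 means truly
    expressing cells are twice as bright as the baseline mixture).
    ``pos_fraction_overrides`` replaces the mixture's positive fraction for
    specific (cell type, marker) pairs, used where the expressing *fraction*
    (not only brightness) differs between compartments.
    """

    name: str
    n_cells: int
    cell_type_proportions: dict[str, float]
    checkpoint_gradient: dict[str, float] = field(default_factory=dict)
    pos_fraction_overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigurationError(f"compartment {self.name!r}: n_cells must be positive")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > _PROP_TOL:
            raise ConfigurationError(
                f"compartment {self.name!r}: cell_type_proportions sum to {total!r}, not 1"
            )
        for ct, p in self.cell_type_proportions.items():
            if p < 0:
                raise ConfigurationError(f"compartment {self.name!r}: negative proportion for {ct!r}")
        for m, g in self.checkpoint_gradient.items():
            if g <= 0:
                raise ConfigurationError(f"compartment {self.name!r}: gradient for {m!r} must be > 0")
        for (ct, m), f in self.pos_fraction_overrides.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(
                    f"compartment {self.name!r}: pos_fraction override for ({ct!r}, {m!r}) outside [0, 1]"
                )


#: Default window for compartment sizes in the bundled presets.
DEFAULT_N_CELLS_RANGE = (800, 6000)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Parameters
    ----------
    panel
        Marker panel to emit (one intensity column per marker).
    compartments
        Test-tissue compartments.
    mixtures
        Map ``(cell_type, marker)`` to its intensity mixture.  Every
        (cell type, marker) pair occurring in the simulation must be covered.
    copositivity
        Per-cell-type TIGIT/PD-1 conditional co-positivity; optional
        per-(cell-type, compartment) overrides in ``copositivity_overrides``.
        The PD-1 positive fraction is derived from the TIGIT marginal and the
        two conditionals, so the three are always consistent.
    spot_diameter_mm
        Diameter of the tissue spot; cell positions are uniform in this disc.
    reference_included
        Whether to also generate a reference tonsil tissue (compartments in
        ``reference_compartments``) on the same slide for normalization.
    """

    panel: MarkerPanel
    compartments: tuple[CompartmentSpec, ...]
    mixtures: dict[tuple[str, str], IntensityMixture]
    copositivity: dict[str, CoPositivity]
    copositivity_overrides: dict[tuple[str, str], CoPositivity] = field(default_factory=dict)
    spot_diameter_mm: float = 4.0
    seed: int = 0
    reference_included: bool = True
    reference_compartments: tuple[CompartmentSpec, ...] = ()
    tissue_id: str = "tissue_1"
    reference_tissue_id: str = "tonsil_ref"
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.spot_diameter_mm <= 0:
            raise ConfigurationError("spot_diameter_mm must be positive")
        if self.reference_included and not self.reference_compartments:
            raise ConfigurationError("reference_included requires reference_compartments")
        object.__setattr__(self, "compartments", tuple(self.compartments))
        object.__setattr__(self, "reference_compartments", tuple(self.reference_compartments))
        self.validate()

    # -- validation ------------------------------------------------------
    def all_compartments(self) -> tuple[CompartmentSpec, ...]:
        return self.compartments + (self.reference_compartments if self.reference_included else ())

    def compartment_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    def mixture_for(self, cell_type: str, marker: str) -> IntensityMixture:
        try:
            return self.mixtures[(cell_type, marker)]
        except KeyError:
            raise ConfigurationError(
                f"no intensity mixture configured for cell type {cell_type!r}, marker {marker!r}"
            ) from None

    def copositivity_for(self, cell_type: str, compartment: str) -> CoPositivity:
        return self.copositivity_overrides.get(
            (cell_type, compartment), self.copositivity[cell_type]
        )

    def tigit_fraction(self, cell_type: str, comp: CompartmentSpec) -> float:
        mix = self.mixture_for(cell_type, "TIGIT")
        return comp.pos_fraction_overrides.get((cell_type, "TIGIT"), mix.pos_fraction)

    def validate(self) -> None:
        """Check mixture coverage and co-positivity feasibility everywhere."""
        ckpt = set(self.panel.checkpoint_markers)
        for comp in self.all_compartments():
            for ct in comp.cell_type_proportions:
                for marker in self.panel.markers:
                    self.mixture_for(ct, marker)
                if {"TIGIT", "PD-1"} <= ckpt:
                    cp = self.copositivity_for(ct, comp.name)
                    cp.joint_table(self.tigit_fraction(ct, comp), cell_type=ct)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def comp_dict(c: CompartmentSpec) -> dict:
            return {
                "name": c.name,
                "n_cells": c.n_cells,
                "cell_type_proportions": dict(c.cell_type_proportions),
                "checkpoint_gradient": dict(c.checkpoint_gradient),
                "pos_fraction_overrides": {
                    f"{ct}|{m}": v for (ct, m), v in c.pos_fraction_overrides.items()
                },
            }

        return {
            "name": self.name,
            "panel": {
                "lineage_markers": list(self.panel.lineage_markers),
                "checkpoint_markers": list(self.panel.checkpoint_markers),
            },
            "compartments": [comp_dict(c) for c in self.compartments],
            "reference_compartments": [comp_dict(c) for c in self.reference_compartments],
            "mixtures": {f"{ct}|{m}": asdict(mx) for (ct, m), mx in self.mixtures.items()},
            "copositivity": {ct: asdict(cp) for ct, cp in self.copositivity.items()},
            "copositivity_overrides": {
                f"{ct}|{comp}": asdict(cp) for (ct, comp), cp in self.copositivity_overrides.items()
            },
            "spot_diameter_mm": self.spot_diameter_mm,
            "seed": self.seed,
            "reference_included": self.reference_included,
            "tissue_id": self.tissue_id,
            "reference_tissue_id": self.reference_tissue_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        def comp_from(cd: dict) -> CompartmentSpec:
            return CompartmentSpec(
                name=cd["name"],
                n_cells=int(cd["n_cells"]),
                cell_type_proportions=dict(cd["cell_type_proportions"]),
                checkpoint_gradient=dict(cd.get("checkpoint_gradient", {})),
                pos_fraction_overrides={
                    tuple(k.split("|")): v
                    for k, v in cd.get("pos_fraction_overrides", {}).items()
                },
            )

        return cls(
            panel=MarkerPanel(
                lineage_markers=tuple(d["panel"]["lineage_markers"]),
                checkpoint_markers=tuple(d["panel"]["checkpoint_markers"]),
            ),
            compartments=tuple(comp_from(c) for c in d["compartments"]),
            reference_compartments=tuple(comp_from(c) for c in d.get("reference_compartments", [])),
            mixtures={
                tuple(k.split("|")): IntensityMixture(**v) for k, v in d["mixtures"].items()
            },
            copositivity={ct: CoPositivity(**v) for ct, v in d["copositivity"].items()},
            copositivity_overrides={
                tuple(k.split("|")): CoPositivity(**v)
                for k, v in d.get("copositivity_overrides", {}).items()
            },
            spot_diameter_mm=float(d["spot_diameter_mm"]),
            seed=int(d["seed"]),
            reference_included=bool(d["reference_included"]),
            tissue_id=d.get("tissue_id", "tissue_1"),
            reference_tissue_id=d.get("reference_tissue_id", "tonsil_ref"),
            name=d.get("name", "custom"),
        )

    def with_seed(self, seed: int) -> "GeneratorConfig":
        d = self.to_dict()
        d["seed"] = int(seed)
        return GeneratorConfig.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
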