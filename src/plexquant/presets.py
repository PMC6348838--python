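"""Bundled cohort presets.

Each preset is a fully resolved :class:`~plexquant.config.GeneratorConfig`
emulating one of the tissue scenarios the pipeline is designed for:

``tonsil``
    Normal tonsil with the four concentric lymph-follicle compartments
    (interfollicular area Ia, marginal/mantle zone Mz, germinal-centre
    periphery Gcp, germinal centre Gcc) plus a reference tonsil spot on the
    same slide.  The encoded marginals are the canonical lymphoid-tissue
    figures this pipeline is validated against: 52% of CD3+ T cells
    TIGIT-positive overall; 47% of CD4, 53% of CD8 and 72% of FOXP3+ T
    cells; >95% of follicular CD4 T cells versus ~47% interfollicular; 78%
    of TIGIT+ cells PD-1-positive and 93.5% of PD-1+ cells TIGIT-positive;
    and a checkpoint brightness gradient rising from Ia over Mz to the
    germinal-centre periphery.
``hashimoto``
    Thyroiditis with germinal-centre formation; checkpoint brightness 2.5x
    the comparable tonsil compartments (germinal_centre vs. Gcp,
    interfollicular vs. Ia), TIGIT:PD-1 roughly balanced.
``sarcoidosis``
    Granulomatous inflammation; TIGIT brighter in the intergranulomatous
    area than inside granulomas, with relative TIGIT excess (ratio > 1).
``lichen_sclerosus`` / ``igg4_pancreatitis`` / ``rheumatoid_arthritis``
    Lymphocyte-dense infiltrates vs. scattered lymphocytes; checkpoints
    upregulated in the dense compartment, PD-1 more than TIGIT (ratio < 1).
``tumour_margin_centre``
    Invasive margin vs. tumour centre; CD8-rich margin with brighter
    checkpoints, sparse tumour centre.
``tma_spot_survey``
    A single 0.6 mm multitumour-array spot for density counting (no
    reference tissue on such spots).

Default seeds: every preset ships with seed 1; pass ``seed=`` to override.
All stochastic generation flows through that single seed.
"""

from __future__ import annotations

from .config import (
    CompartmentSpec,
    CoPositivity,
    GeneratorConfig,
    IntensityMixture,
)
from .panel import (
    CELL_TYPES,
    CELL_TYPE_DEFINING_MARKERS,
    DEFAULT_PANEL,
)

PRESET_NAMES = (
    "tonsil",
    "hashimoto",
    "sarcoidosis",
    "lichen_sclerosus",
    "igg4_pancreatitis",
    "rheumatoid_arthritis",
    "tumour_margin_centre",
    "tma_spot_survey",
)

# Lognormal parameters (log scale, arbitrary scanner units).
_LINEAGE_NEG = (0.0, 0.35)
_LINEAGE_POS = (2.5, 0.35)
_CHECKPOINT_NEG = (0.0, 0.40)
_CHECKPOINT_POS = {"TIGIT": (2.2, 0.35), "PD-1": (2.0, 0.35)}

#: Baseline TIGIT-expressing fraction per cell type (compartment overrides
#: in the presets adjust CD4 T cells, whose expressing fraction differs
#: between follicular and interfollicular locations).
_TIGIT_FRACTION = {
    "CD4_T": 0.47,
    "CD8_T": 0.53,
    "FOXP3_Treg": 0.72,
    "CD3_T": 0.667,
    "CD56_NK": 0.40,
    "CD20_B": 0.0,
    "CD11c_DC": 0.0,
    "CD68_Mac": 0.0,
    "other": 0.0,
}

#: Default conditional co-positivity of the checkpoint pair.
_DEFAULT_COPOS = CoPositivity(p_pd1_given_tigit=0.78, p_tigit_given_pd1=0.935)
#: Follicular CD4 T cells are almost universally TIGIT-positive; slightly
#: tighter conditionals keep the implied 2x2 table feasible at that marginal.
_FOLLICULAR_CD4_COPOS = CoPositivity(p_pd1_given_tigit=0.80, p_tigit_given_pd1=0.96)


def _build_mixtures() -> dict[tuple[str, str], IntensityMixture]:
    """One mixture per (cell type, marker): lineage positivity is defined by
    the cell type; checkpoint positive fractions come from the table above."""
    mixtures: dict[tuple[str, str], IntensityMixture] = {}
    for ct in CELL_TYPES:
        defining = set(CELL_TYPE_DEFINING_MARKERS[ct])
        for marker in DEFAULT_PANEL.lineage_markers:
            mixtures[(ct, marker)] = IntensityMixture(
                neg_log_mean=_LINEAGE_NEG[0],
                neg_log_sd=_LINEAGE_NEG[1],
                pos_log_mean=_LINEAGE_POS[0],
                pos_log_sd=_LINEAGE_POS[1],
                pos_fraction=1.0 if marker in defining else 0.0,
            )
        for marker in DEFAULT_PANEL.checkpoint_markers:
            pos_mu, pos_sd = _CHECKPOINT_POS[marker]
            frac = _TIGIT_FRACTION[ct] if marker == "TIGIT" else 0.0  # PD-1 derived
            mixtures[(ct, marker)] = IntensityMixture(
                neg_log_mean=_CHECKPOINT_NEG[0],
                neg_log_sd=_CHECKPOINT_NEG[1],
                pos_log_mean=pos_mu,
                pos_log_sd=pos_sd,
                pos_fraction=frac,
            )
    return mixtures


def _props(**kwargs: float) -> dict[str, float]:
    total = sum(kwargs.values())
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"preset proportions sum to {total}")
    return kwargs


# Tonsil compartment brightness gradients: the expressing population grows
# brighter from the interfollicular area towards the germinal-centre
# periphery (the follicular light zone), slightly dimmer in the centre.
_TONSIL_GRADIENT = {
    "Ia": {"TIGIT": 1.0, "PD-1": 1.0},
    "Mz": {"TIGIT": 1.7, "PD-1": 1.9},
    "Gcp": {"TIGIT": 3.0, "PD-1": 3.6},
    "Gcc": {"TIGIT": 2.8, "PD-1": 3.4},
}

# CD4 expressing-fraction overrides: ~47% interfollicular baseline, reduced
# in the mantle zone, near-universal in the follicle (Gcp/Gcc).  The mantle
# value is solved so the pooled CD4 marginal equals the 47% baseline under
# the compartment composition below.
_TONSIL_CD4_TIGIT = {"Mz": 0.352, "Gcp": 0.96, "Gcc": 0.96}


def _tonsil_compartments(scale: float = 1.0) -> tuple[CompartmentSpec, ...]:
    comps = []
    spec = [
        ("Ia", 4000, _props(CD4_T=0.44, CD8_T=0.20, FOXP3_Treg=0.06, CD3_T=0.08,
                            CD20_B=0.12, CD56_NK=0.02, CD11c_DC=0.03, CD68_Mac=0.03,
                            other=0.02)),
        ("Mz", 2500, _props(CD20_B=0.45, CD4_T=0.39, CD8_T=0.05, FOXP3_Treg=0.02,
                            CD3_T=0.02, CD56_NK=0.01, CD11c_DC=0.02, CD68_Mac=0.02,
                            other=0.02)),
        ("Gcp", 1500, _props(CD20_B=0.62, CD4_T=0.07, CD8_T=0.04, FOXP3_Treg=0.03,
                             CD3_T=0.02, CD56_NK=0.01, CD11c_DC=0.05, CD68_Mac=0.08,
                             other=0.08)),
        ("Gcc", 2000, _props(CD20_B=0.70, CD4_T=0.065, CD8_T=0.02, FOXP3_Treg=0.02,
                             CD3_T=0.015, CD56_NK=0.0, CD11c_DC=0.04, CD68_Mac=0.10,
                             other=0.04)),
    ]
    for name, n, props in spec:
        overrides = {}
        if name in _TONSIL_CD4_TIGIT:
            overrides[("CD4_T", "TIGIT")] = _TONSIL_CD4_TIGIT[name]
        comps.append(
            CompartmentSpec(
                name=name,
                n_cells=max(1, round(n * scale)),
                cell_type_proportions=props,
                checkpoint_gradient=dict(_TONSIL_GRADIENT[name]),
                pos_fraction_overrides=overrides,
            )
        )
    return tuple(comps)


_FOLLICULAR_OVERRIDES = {
    ("CD4_T", "Gcp"): _FOLLICULAR_CD4_COPOS,
    ("CD4_T", "Gcc"): _FOLLICULAR_CD4_COPOS,
}


def _base_kwargs(seed: int) -> dict:
    # The follicular-CD4 overrides must accompany every preset that carries
    # the tonsil reference tissue (its Gcp/Gcc compartments encode the
    # near-universal CD4 TIGIT positivity).
    return dict(
        panel=DEFAULT_PANEL,
        mixtures=_build_mixtures(),
        copositivity={ct: _DEFAULT_COPOS for ct in CELL_TYPES},
        copositivity_overrides=dict(_FOLLICULAR_OVERRIDES),
        seed=seed,
        reference_compartments=_tonsil_compartments(scale=0.5),
        reference_tissue_id="tonsil_ref",
    )


def _tonsil(seed: int) -> GeneratorConfig:
    kw = _base_kwargs(seed)
    return GeneratorConfig(
        compartments=_tonsil_compartments(),
        spot_diameter_mm=4.0,
        reference_included=True,
        tissue_id="tonsil_test",
        name="tonsil",
        **kw,
    )


#: Hashimoto thyroiditis: checkpoint brightness 2.5x the comparable tonsil
#: compartments (germinal_centre vs. Gcp, interfollicular vs. Ia).
HASHIMOTO_FACTOR = 2.5


def _hashimoto(seed: int) -> GeneratorConfig:
    kw = _base_kwargs(seed)
    f = HASHIMOTO_FACTOR
    comps = (
        CompartmentSpec(
            name="germinal_centre",
            n_cells=1800,
            cell_type_proportions=_props(CD20_B=0.55, CD4_T=0.15, CD8_T=0.05,
                                         FOXP3_Treg=0.04, CD3_T=0.03, CD56_NK=0.01,
                                         CD11c_DC=0.04, CD68_Mac=0.08, other=0.05),
            checkpoint_gradient={"TIGIT": _TONSIL_GRADIENT["Gcp"]["TIGIT"] * f,
                                 "PD-1": _TONSIL_GRADIENT["Gcp"]["PD-1"] * f},
            pos_fraction_overrides={("CD4_T", "TIGIT"): 0.96},
        ),
        CompartmentSpec(
            name="interfollicular",
            n_cells=2500,
            cell_type_proportions=_props(CD4_T=0.40, CD8_T=0.18, FOXP3_Treg=0.06,
                                         CD3_T=0.06, CD20_B=0.15, CD56_NK=0.02,
                                         CD11c_DC=0.04, CD68_Mac=0.05, other=0.04),
            checkpoint_gradient={"TIGIT": _TONSIL_GRADIENT["Ia"]["TIGIT"] * f,
                                 "PD-1": _TONSIL_GRADIENT["Ia"]["PD-1"] * f},
        ),
    )
    kw["copositivity_overrides"][("CD4_T", "germinal_centre")] = _FOLLICULAR_CD4_COPOS
    return GeneratorConfig(
        compartments=comps,
        spot_diameter_mm=4.0,
        reference_included=True,
        tissue_id="hashimoto_1",
        name="hashimoto",
        **kw,
    )


def _sarcoidosis(seed: int) -> GeneratorConfig:
    kw = _base_kwargs(seed)
    comps = (
        CompartmentSpec(
            name="granuloma",
            n_cells=1500,
            cell_type_proportions=_props(CD68_Mac=0.40, CD4_T=0.25, CD8_T=0.10,
                                         FOXP3_Treg=0.05, CD3_T=0.05, CD20_B=0.05,
                                         CD11c_DC=0.05, CD56_NK=0.01, other=0.04),
            # TIGIT relatively in excess over PD-1 throughout (ratio > 1),
            # and dimmer inside granulomas than between them.
            checkpoint_gradient={"TIGIT": 1.2, "PD-1": 0.5},
        ),
        CompartmentSpec(
            name="intergranuloma",
            n_cells=2000,
            cell_type_proportions=_props(CD4_T=0.30, CD8_T=0.15, FOXP3_Treg=0.06,
                                         CD3_T=0.06, CD20_B=0.20, CD68_Mac=0.08,
                                         CD11c_DC=0.05, CD56_NK=0.02, other=0.08),
            checkpoint_gradient={"TIGIT": 2.2, "PD-1": 0.9},
        ),
    )
    return GeneratorConfig(
        compartments=comps,
        spot_diameter_mm=4.0,
        reference_included=True,
        tissue_id="sarcoidosis_1",
        name="sarcoidosis",
        **kw,
    )


def _infiltrate_preset(name: str, seed: int, tigit_scale: float, pd1_scale: float) -> GeneratorConfig:
    """Shared shape for the scattered-vs-dense inflammatory presets: PD-1
    more strongly upregulated than TIGIT in lymphocyte-dense areas."""
    kw = _base_kwargs(seed)
    comps = (
        CompartmentSpec(
            name="lymphocytic_infiltration",
            n_cells=3000,
            cell_type_proportions=_props(CD4_T=0.32, CD8_T=0.18, FOXP3_Treg=0.05,
                                         CD3_T=0.05, CD20_B=0.20, CD68_Mac=0.08,
                                         CD11c_DC=0.04, CD56_NK=0.02, other=0.06),
            checkpoint_gradient={"TIGIT": 1.6 * tigit_scale, "PD-1": 2.6 * pd1_scale},
        ),
        CompartmentSpec(
            name="scattered",
            n_cells=900,
            cell_type_proportions=_props(CD4_T=0.15, CD8_T=0.10, FOXP3_Treg=0.02,
                                         CD3_T=0.03, CD20_B=0.05, CD68_Mac=0.10,
                                         CD11c_DC=0.03, CD56_NK=0.02, other=0.50),
            checkpoint_gradient={"TIGIT": 0.8 * tigit_scale, "PD-1": 1.0 * pd1_scale},
        ),
    )
    return GeneratorConfig(
        compartments=comps,
        spot_diameter_mm=4.0,
        reference_included=True,
        tissue_id=f"{name}_1",
        name=name,
        **kw,
    )


def _tumour_margin_centre(seed: int) -> GeneratorConfig:
    kw = _base_kwargs(seed)
    comps = (
        CompartmentSpec(
            name="invasive_margin",
            n_cells=3000,
            cell_type_proportions=_props(CD8_T=0.35, CD4_T=0.25, FOXP3_Treg=0.05,
                                         CD3_T=0.05, CD20_B=0.05, CD68_Mac=0.10,
                                         CD11c_DC=0.05, CD56_NK=0.02, other=0.08),
            checkpoint_gradient={"TIGIT": 1.8, "PD-1": 1.9},
        ),
        CompartmentSpec(
            name="tumour_centre",
            n_cells=900,
            cell_type_proportions=_props(CD8_T=0.12, CD4_T=0.10, FOXP3_Treg=0.03,
                                         CD3_T=0.03, CD20_B=0.02, CD68_Mac=0.15,
                                         CD11c_DC=0.05, CD56_NK=0.02, other=0.48),
            checkpoint_gradient={"TIGIT": 0.8, "PD-1": 0.8},
        ),
    )
    return GeneratorConfig(
        compartments=comps,
        spot_diameter_mm=4.0,
        reference_included=True,
        tissue_id="carcinoma_1",
        name="tumour_margin_centre",
        **kw,
    )


def _tma_spot_survey(seed: int) -> GeneratorConfig:
    kw = _base_kwargs(seed)
    kw["reference_compartments"] = ()
    comps = (
        CompartmentSpec(
            name="spot",
            n_cells=800,
            cell_type_proportions=_props(other=0.60, CD8_T=0.12, CD4_T=0.10,
                                         FOXP3_Treg=0.02, CD3_T=0.03, CD20_B=0.05,
                                         CD68_Mac=0.05, CD11c_DC=0.02, CD56_NK=0.01),
            checkpoint_gradient={"TIGIT": 1.0, "PD-1": 1.0},
        ),
    )
    return GeneratorConfig(
        compartments=comps,
        spot_diameter_mm=0.6,
        reference_included=False,
        tissue_id="tma_spot_1",
        name="tma_spot_survey",
        **kw,
    )


_BUILDERS = {
    "tonsil": _tonsil,
    "hashimoto": _hashimoto,
    "sarcoidosis": _sarcoidosis,
    "lichen_sclerosus": lambda seed: _infiltrate_preset("lichen_sclerosus", seed, 1.0, 1.0),
    "igg4_pancreatitis": lambda seed: _infiltrate_preset("igg4_pancreatitis", seed, 1.1, 1.2),
    "rheumatoid_arthritis": lambda seed: _infiltrate_preset("rheumatoid_arthritis", seed, 0.9, 1.1),
    "tumour_margin_centre": _tumour_margin_centre,
    "tma_spot_survey": _tma_spot_survey,
}


def make_preset(name: str, seed: int = 1) -> GeneratorConfig:
    """Return the named preset configuration.

    Raises :class:`KeyError` listing the valid names if ``name`` is unknown.
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
    return builder(seed)
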