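"""Recovery experiments: rerun the full pipeline on a synthetic cohort and
measure the gated marginals it reports.

These are the package's validation workloads: the tonsil preset encodes the
canonical lymphoid-tissue checkpoint marginals, and :func:`tonsil_recovery`
runs calibration → gating → counting end to end and returns what the
pipeline *measured*, together with the realized population sizes (for
binomial error bars).  Nothing here reads the generator's truth sidecar —
recovery uses only what a real slide would provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gating import calibrate_panel, call_positivity
from .presets import make_preset
from .quantify import coexpression_fractions, relative_expression, t_subtype_mask
from .simulate import generate_cells

#: Lymph-follicle compartments of the tonsil preset.
FOLLICULAR = ("Gcp", "Gcc")


@dataclass(frozen=True)
class Marginal:
    """A measured percentage with its population size."""

    percent: float
    n: int


def tonsil_recovery(seed: int) -> dict[str, Marginal]:
    """Run the pipeline on the tonsil preset and return its gated marginals.

    Keys:

    - ``cd3_tigit``: % of CD3+ cells above the TIGIT cutoff
    - ``cd4_tigit`` / ``cd8_tigit`` / ``foxp3_tigit``: % of the gated
      T-cell subtype above the TIGIT cutoff (pooled over compartments)
    - ``cd4_tigit_follicular`` / ``cd4_tigit_interfollicular``: the same for
      CD4 T cells inside lymph follicles (Gcp+Gcc) and in the
      interfollicular area
    - ``pd1_given_tigit`` / ``tigit_given_pd1``: conditional coexpression
      percentages among gated cells
    - ``reference_re_tigit`` / ``reference_re_pd1``: relative expression of
      the reference population against itself (identity check, exactly 100)
    """
    cfg = make_preset("tonsil", seed=seed)
    sim = generate_cells(cfg)
    cells = sim.cells
    thresholds = calibrate_panel(cells, seed=seed)
    pheno = call_positivity(cells, thresholds)
    merged = cells.merge(pheno, on="cell_id")
    test = merged.loc[merged["tissue_role"] == "test"]

    out: dict[str, Marginal] = {}

    cd3 = test.loc[test["CD3_pos"]]
    out["cd3_tigit"] = Marginal(100.0 * cd3["TIGIT_pos"].mean(), len(cd3))

    for key, subtype in (
        ("cd4_tigit", "CD4_T"),
        ("cd8_tigit", "CD8_T"),
        ("foxp3_tigit", "FOXP3_Treg"),
    ):
        sub = test.loc[t_subtype_mask(test, subtype)]
        out[key] = Marginal(100.0 * sub["TIGIT_pos"].mean(), len(sub))

    cd4 = test.loc[t_subtype_mask(test, "CD4_T")]
    foll = cd4.loc[cd4["compartment"].isin(FOLLICULAR)]
    inter = cd4.loc[cd4["compartment"] == "Ia"]
    out["cd4_tigit_follicular"] = Marginal(100.0 * foll["TIGIT_pos"].mean(), len(foll))
    out["cd4_tigit_interfollicular"] = Marginal(100.0 * inter["TIGIT_pos"].mean(), len(inter))

    co = coexpression_fractions(test)
    out["pd1_given_tigit"] = Marginal(100.0 * co.frac_tigit_pos_that_are_pd1_pos, co.n_tigit_pos)
    out["tigit_given_pd1"] = Marginal(100.0 * co.frac_pd1_pos_that_are_tigit_pos, co.n_pd1_pos)

    ref = merged.loc[(merged["tissue_role"] == "reference") & (merged["compartment"] == "Gcp")]
    out["reference_re_tigit"] = Marginal(relative_expression(ref, ref, "TIGIT"), len(ref))
    out["reference_re_pd1"] = Marginal(relative_expression(ref, ref, "PD-1"), len(ref))
    return out


def tonsil_gradient(seed: int) -> pd.DataFrame:
    """RE[TIGIT] per (cell type, compartment) on the tonsil preset test
    tissue: the compartment brightness gradient as the pipeline measures it."""
    from .quantify import summarize_compartments

    cfg = make_preset("tonsil", seed=seed)
    sim = generate_cells(cfg)
    thresholds = calibrate_panel(sim.cells, seed=seed)
    pheno = call_positivity(sim.cells, thresholds)
    s = summarize_compartments(sim.cells, pheno)
    return s.loc[s["tissue_id"] == cfg.tissue_id]
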