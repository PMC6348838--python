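"""Panel reports: per-cell-type RE/ratio tables and bar panels.

Renders the standard compartment panel: for each T-cell subtype, grouped
bars of RE[TIGIT] and RE[PD-1] per compartment (reference = 100%) with the
TIGIT:PD-1 ratio drawn as a black marker on a secondary axis.  The CSV
table is written deterministically (fixed column order, sorted rows) so a
rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .errors import ReportError

_TABLE_COLUMNS = [
    "tissue_id",
    "compartment",
    "cell_type",
    "n_cells",
    "low_n",
    "mean_raw_TIGIT",
    "mean_raw_PD-1",
    "RE_TIGIT",
    "RE_PD-1",
    "ratio_tigit_pd1",
]


def panel_report(
    summaries: pd.DataFrame,
    comparisons: list | None,
    output_dir: str | Path,
    group_order: list[str] | None = None,
) -> dict[str, Path]:
    """Write the summary table, comparison table, and one panel per cell type.

    Returns a map of artifact name → path.  Raises :class:`ReportError` on
    empty summaries.
    """
    if summaries is None or summaries.empty:
        raise ReportError("cannot render a panel report from empty summaries")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    table = summaries.copy()
    cols = [c for c in _TABLE_COLUMNS if c in table.columns]
    table = table[cols].sort_values(["tissue_id", "cell_type", "compartment"]).reset_index(drop=True)
    table_path = out / "compartment_summaries.csv"
    table.to_csv(table_path, index=False)
    artifacts["summary_table"] = table_path

    if comparisons:
        comp_rows = [
            {
                "cell_type": c.cell_type,
                "marker": c.marker,
                "groups": "|".join(c.grouping),
                "F_stat": c.F_stat,
                "p_value": c.p_value,
                "stars": c.stars,
                "n_per_group": "|".join(str(n) for n in c.n_per_group),
            }
            for c in comparisons
        ]
        comp_path = out / "group_comparisons.csv"
        pd.DataFrame(comp_rows).to_csv(comp_path, index=False)
        artifacts["comparison_table"] = comp_path

    for cell_type, sub in table.groupby("cell_type", sort=True):
        order = group_order or sorted(sub["compartment"].unique())
        sub = sub.set_index("compartment").loc[[c for c in order if c in sub["compartment"].values]]
        fig, ax = plt.subplots(figsize=(6, 4))
        x = range(len(sub))
        width = 0.35
        ax.bar([i - width / 2 for i in x], sub["RE_TIGIT"], width, color="forestgreen", label="TIGIT")
        ax.bar([i + width / 2 for i in x], sub["RE_PD-1"], width, color="firebrick", label="PD-1")
        ax.set_xticks(list(x))
        ax.set_xticklabels(sub.index)
        ax.set_ylabel("relative expression (% of reference)")
        ax.axhline(100, color="grey", lw=0.8, ls="--")
        ax.set_title(cell_type)
        ax.legend(loc="upper left")
        if "ratio_tigit_pd1" in sub.columns:
            ax2 = ax.twinx()
            ax2.plot(list(x), sub["ratio_tigit_pd1"], "k_", markersize=18, label="TIGIT:PD-1")
            ax2.set_ylabel("TIGIT : PD-1 ratio")
            ax2.set_ylim(bottom=0)
        fig.tight_layout()
        png_path = out / f"panel_{cell_type}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        artifacts[f"panel_{cell_type}"] = png_path
    return artifacts
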