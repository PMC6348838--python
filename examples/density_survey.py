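"""Cell densities on tissue spots and at the invasive margin.

Counts on a circular tissue-microarray spot convert to cells/mm² through
the spot area; tumour-section regions report CD8+TIGIT+ cells per 0.1 mm².
The margin/centre preset encodes the typical pattern: a dense, bright
infiltrate at the invasive margin and sparse T cells in the tumour centre.
"""

from plexquant import (
    SpotGeometry,
    calibrate_panel,
    call_positivity,
    density,
    density_per_0p1mm2,
    generate_cells,
    make_preset,
)
from plexquant.quantify import t_subtype_mask

# --- 0.6 mm multitumour-array spot: TIGIT+ cells per mm² ---------------
sim = generate_cells(make_preset("tma_spot_survey", seed=1))
# no reference tissue on survey spots: gate with thresholds from the spot
thresholds = calibrate_panel(sim.cells, seed=1)
pheno = call_positivity(sim.cells, thresholds)
spot = SpotGeometry(0.6)
n_tigit = int(pheno.TIGIT_pos.sum())
print(f"0.6 mm spot: {n_tigit} TIGIT+ cells on {spot.area_mm2:.4f} mm² "
      f"-> {density(n_tigit, spot):.0f} cells/mm²")

# --- invasive margin vs tumour centre: CD8+TIGIT+ per 0.1 mm² ----------
sim = generate_cells(make_preset("tumour_margin_centre", seed=1))
thresholds = calibrate_panel(sim.cells, seed=1)
pheno = call_positivity(sim.cells, thresholds)
merged = sim.cells.merge(pheno, on="cell_id")
test = merged[merged.tissue_role == "test"]
print("\nCD8+TIGIT+ density per 0.1 mm² (assumed region areas):")
for comp, area_mm2 in (("invasive_margin", 1.0), ("tumour_centre", 1.0)):
    sub = test[test.compartment == comp]
    count = int((t_subtype_mask(sub, "CD8_T") & sub.TIGIT_pos).sum())
    print(f"  {comp:16s} {count:4d} cells in {area_mm2} mm² "
          f"-> {density_per_0p1mm2(count, area_mm2):.1f} per 0.1 mm²")
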