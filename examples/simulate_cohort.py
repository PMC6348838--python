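"""Generate a synthetic tonsil cohort and look at its structure.

The tonsil preset emulates a multiplex-stained slide: a test tonsil spot
with the four concentric lymph-follicle compartments (Ia, Mz, Gcp, Gcc)
plus a reference tonsil spot used later for normalization.  Each row is one
cell with raw fluorescence intensities for ten markers.
"""

from plexquant import generate_cells, make_preset

config = make_preset("tonsil", seed=1)
sim = generate_cells(config)

print(f"cells generated: {len(sim.cells)}")
print("\ncells per tissue/compartment:")
print(sim.cells.groupby(["tissue_role", "compartment"]).size().to_string())

truth = sim.cells.merge(sim.truth, on="cell_id")
print("\nsimulated cell-type composition (test tissue):")
comp = truth.loc[truth.tissue_role == "test", "true_cell_type"].value_counts()
print(comp.to_string())

print("\nfirst rows of the measurement table (what the pipeline sees):")
print(sim.cells[["cell_id", "compartment", "CD3", "CD20", "TIGIT", "PD-1"]].head(3).round(2).to_string(index=False))
# The truth sidecar (sim.truth) exists only for validation; the analysis
# below never reads it.
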