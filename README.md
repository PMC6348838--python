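# plexquant

Compartment-resolved quantification of multiplex immunofluorescence cell
tables, built around the immune checkpoint receptors **TIGIT** and **PD-1**.

Pathology studies of checkpoint expression measure, for every segmented
cell on a scanned slide, one raw fluorescence intensity per marker (here a
ten-plex panel: CD3, CD4, CD8, FOXP3, CD20, CD56, CD11c, CD68, TIGIT,
PD-1), with cells grouped into pathologist-drawn tissue compartments —
e.g. the concentric zones of a lymph follicle (interfollicular area *Ia*,
marginal/mantle zone *Mz*, germinal-centre periphery *Gcp*, germinal
centre *Gcc*), granuloma vs. intergranuloma, or invasive margin vs. tumour
centre. `plexquant` turns those per-cell tables into the standard readouts:

- **Threshold calibration** — for each marker, the cutoff is the brightest
  "false positive" reading among 50–200 cells expected to lack the marker
  (B cells for TIGIT/PD-1); a cell is positive only if it strictly exceeds
  the cutoff.
- **Phenotyping** — boolean marker calls are resolved into cell types by a
  fixed precedence (FOXP3⁺ regulatory T cells first, then CD8/CD4/CD3 T
  cells, B, NK, dendritic cells, macrophages).
- **Relative expression (RE)** — mean raw intensity of a test population
  as a percentage of reference tonsil germinal-centre cells carried on the
  same slide: `RE = 100 · mean(test) / mean(reference)`. The
  **TIGIT:PD-1 ratio** is `RE[TIGIT] / RE[PD-1]` within one population.
- **Coexpression** — conditional fractions P(PD-1⁺ | TIGIT⁺) and
  P(TIGIT⁺ | PD-1⁺) among gated cells.
- **Densities** — cells/mm² on circular TMA spots (`count / (π·(d/2)²)`)
  and cells per 0.1 mm² in arbitrary regions.
- **Statistics** — one-way ANOVA of expression across compartments with
  the usual significance tiers (`*` p ≤ 0.05, `**` p ≤ 0.001, `***`
  p ≤ 0.0001), plus an optional Welch/Holm post-hoc extension.

Because per-cell scanner exports are rarely public, the package includes a
first-class **synthetic cohort generator**: each (cell type, marker) pair
draws from a two-component lognormal mixture, TIGIT/PD-1 positivity is
drawn jointly from configured conditional co-positivities, and compartment
gradients brighten the expressing population zone by zone. Bundled presets
(`tonsil`, `hashimoto`, `sarcoidosis`, `lichen_sclerosus`,
`igg4_pancreatitis`, `rheumatoid_arthritis`, `tumour_margin_centre`,
`tma_spot_survey`) encode the canonical tissue scenarios; the tonsil
preset's defaults encode the classic lymphoid-tissue marginals (≈52% of
CD3⁺ T cells TIGIT⁺; 47%/53%/72% for CD4/CD8/FOXP3 subtypes; >95%
follicular vs. ~47% interfollicular CD4; >70% of TIGIT⁺ cells PD-1⁺ and
>90% of PD-1⁺ cells TIGIT⁺), so the whole pipeline can be validated by
recovering them.

## Worked example

```python
from plexquant import (make_preset, generate_cells, calibrate_panel,
                       call_positivity, summarize_compartments)

sim = generate_cells(make_preset("tonsil", seed=1))
thresholds = calibrate_panel(sim.cells, seed=1)
pheno = call_positivity(sim.cells, thresholds)
summaries = summarize_compartments(sim.cells, pheno)
print(summaries[summaries.tissue_id == "tonsil_test"]
      [["compartment", "cell_type", "n_cells", "RE_TIGIT", "RE_PD-1",
        "ratio_tigit_pd1"]].round(1))
```

prints (CD4 rows shown):

```
compartment  cell_type  n_cells  RE_TIGIT  RE_PD-1  ratio_tigit_pd1
         Ia      CD4_T     1780      17.8     15.3              1.2
         Mz      CD4_T     1021      22.1     22.3              1.0
        Gcp      CD4_T      107      96.7     96.3              1.0
        Gcc      CD4_T      126      78.4     96.8              0.8
```

Read: relative to the reference germinal-centre periphery (= 100%), CD4 T
cells in the interfollicular area express TIGIT at ~18% — expression rises
steeply toward the follicle (Ia < Mz < Gcp), and the TIGIT:PD-1 ratio
drifts above 1 outside the follicle, i.e. TIGIT is relatively higher
there. The `examples/` directory contains one short narrative script per
capability (simulation, gating, quantification, compartment statistics,
densities); each prints the numbers it computes and what they mean.

A thin CLI wraps the same library calls:

```sh
plexquant simulate tonsil --seed 1 --out out/
plexquant run --preset tonsil --seed 1 --out out/
```

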