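# Methods

## The measurement model

`plexquant` operates on per-cell intensity tables: one row per segmented
cell with a tissue identifier, a tissue role (`test` or `reference`), a
pathologist-assigned compartment label, a position in µm, and one raw
fluorescence intensity per marker in arbitrary scanner units. The package
deliberately starts *after* image segmentation — pixels, spectral
unmixing and dye chemistry are out of scope — because every downstream
scientific quantity (thresholds, relative expression, ratios, densities)
is defined on the per-cell table alone.

Raw fluorescence units are scanner-specific and carry no absolute
meaning. All reported quantities are therefore either fractions of gated
cells, ratios, or percentages of a same-slide reference population; every
one of them is invariant under a global rescaling of intensities (a
tested property).

## Threshold calibration

Positivity cutoffs follow the negative-control rule: for each marker, the
raw intensity of 50–200 cells *expected to lack the marker* is measured,
and the brightest such "false positive" reading becomes the cutoff. A
cell is called positive only when its intensity **strictly exceeds** the
cutoff — a cell exactly at the cutoff equals a known-negative cell and is
therefore negative. The window [50, 200] is enforced as a hard
precondition (configurable).

Negative-control selection is rule-driven and seeded. TIGIT and PD-1
negatives are drawn from B cells (CD20-gated), which do not express
either receptor; lineage markers calibrate against a provisional gate
(top decile of the complementary lineage marker's raw intensity), which
bootstraps calibration before any threshold exists. Calibration runs in
two passes: lineage markers first, then the checkpoints against the
threshold-gated B-cell pool.

One subtlety matters for the max-based rule: it is maximally sensitive to
a single contaminant. With threshold-only CD20 gating, the occasional
spuriously CD20-bright T cell (the ~0.5% tail above any max-of-n cutoff)
would enter the "negative" pool carrying genuine TIGIT signal and inflate
the cutoff several-fold. Checkpoint negative controls are therefore
gated **CD20⁺ and CD3⁻** — the standard immunophenotyping definition of a
pure B cell. Rules are configurable per marker (`NegativeControlRule`,
with `exclude_markers`).

Thresholds are calibrated once per slide by default: a generated table
represents one slide that carries both the test tissue and the reference
tonsil spot, mirroring the reference-on-each-slide TMA design. Per-tissue
calibration is available by running `calibrate_panel` on per-tissue
subsets.

## Phenotyping

Cell types are assigned from the boolean calls by fixed precedence:
FOXP3⁺ → regulatory T cell; else CD8⁺ → cytotoxic T; else CD4⁺ → helper
T; else CD3⁺ → T cell; else CD20⁺ → B; else CD56⁺ → NK; else CD11c⁺ →
dendritic; else CD68⁺ → macrophage; else *other*. The precedence resolves
multi-positive cells deterministically (e.g. CD4⁺CD8⁺ → CD8_T) and is
tested against an enumeration of all 2⁸ lineage-call combinations.

For *population-level readouts* of the T-cell subtypes, the package uses
`t_subtype_mask`: a gated "CD4⁺ T cell" must carry the CD3 call in
addition to the CD4_T label. The precedence alone labels any CD4⁺ cell
CD4_T; in compartments where another lineage vastly outnumbers the
subtype (B-cell-rich germinal centres, ~12:1), the small spurious-call
rate inherent to any max-of-negatives cutoff would otherwise dilute the
population by several percent. Requiring the CD3 call restores the
field's definition of the population without touching the labelling rule.

## Relative expression and ratios

`RE = 100 · mean(test) / mean(reference)`, with the arithmetic mean of
raw intensities over *all* cells of the scoped type in the compartment
(no trimming, no outlier removal). The reference population is the
reference tonsil's **germinal-centre periphery (Gcp)** by default — the
compartment with the brightest checkpoint expression, so most test
populations score below 100% — and is **type-matched**: test CD8 T cells
are normalized to reference CD8 T cells. Both choices are switchable
(`ReferenceSpec(compartment="Gcc")`, `pooled_reference=True`). Computing
the ratio before multiplying by 100 makes a population measured against
itself exactly 100.0 in floating point.

The TIGIT:PD-1 ratio is `RE[TIGIT] / RE[PD-1]`. Computing it from RE
values rather than raw means is a deliberate choice: both markers are
normalized against the same reference population, so the two conventions
differ only by the fixed factor `mean_ref(PD-1)/mean_ref(TIGIT)`; the
RE-based ratio is 1 for a population expressing both markers at
reference level, which is the interpretable anchor.

Undefined quantities (empty conditioning populations, zero reference
means, zero-cell types) are reported as errors or `None`, never silently
as 0 or infinity. Compartment summaries flag populations with n < 20 as
`low_n` (default, configurable); the flag is advisory, not a filter.

## Densities

Spot densities assume circular punches: `density = count / (π·(d/2)²)`,
with the 0.6 mm multitumour-spot and 4 mm microenvironment-spot diameters
as the common cases. `density_per_0p1mm2` converts counts in arbitrary
regions to the conventional per-0.1 mm² scale. Both are exact arithmetic
and tested against the closed form at 1e-9 relative tolerance.

## Statistics

Compartment and group differences use classical one-way fixed-effects
ANOVA, implemented from the sum-of-squares decomposition and verified in
tests against both an independent from-scratch oracle (1e-10) and
`scipy.stats.f_oneway`. Degenerate inputs: all groups internally constant
gives F = 0, p = 1 when means agree (and p → 0 otherwise); groups with
fewer than two observations are rejected. Significance tiers are
inclusive: `*` p ≤ 0.05, `**` p ≤ 0.001, `***` p ≤ 0.0001, else `n.s.`.

When a single tissue is analysed, comparisons operate on per-cell
intensity values within compartments; with multiple patients, per-patient
RE values are the appropriate unit (`compare_groups` on a per-patient
summary table). Pairwise Welch t-tests with Holm adjustment are an
explicitly labelled post-hoc extension, off by default; no mixed-effects
or broader multiple-testing machinery is in scope.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not images:

- **Intensity model.** Each (cell type, marker) draws from a
  two-component lognormal mixture — fluorescence intensities are positive
  and right-skewed, and gating needs exactly a dim background population
  plus a bright expressing population. Defaults put lineage markers at
  log-mean 0 (sd 0.35) background and 2.5 (sd 0.35) positive; checkpoints
  at background sd 0.40 with positive log-means 2.2 (TIGIT) and 2.0
  (PD-1). These separations (≥5 background log-sds) make calibration
  near-lossless: the max-of-200 cutoff misses <1% of truth positives and
  admits ~0.5% false positives.
- **Compartment gradients.** A per-compartment factor multiplies the
  *median intensity* of the expressing population of each checkpoint
  marker (implemented as `pos_log_mean + ln(factor)`), so "2.5× brighter"
  means what it says on the intensity scale. Tonsil TIGIT factors are
  1.0 (Ia), 1.7 (Mz), 3.0 (Gcp), 2.8 (Gcc) — rising into the follicle,
  brightest at the periphery; PD-1 rises slightly more steeply, which
  drives the TIGIT:PD-1 ratio above 1 outside the follicle.
- **Co-positivity.** Given the TIGIT marginal p_T and the two conditionals
  c1 = P(PD-1⁺|TIGIT⁺), c2 = P(TIGIT⁺|PD-1⁺), the joint 2×2 table of the
  two indicators is fully determined (the PD-1 marginal is derived as
  c1·p_T/c2, never configured separately, so the three are always
  consistent); cells draw directly from that table. A feasibility check
  (P(TIGIT⁻PD-1⁺) ≤ 1−p_T) rejects impossible configurations naming the
  cell type. Defaults: (0.78, 0.935); follicular CD4 T cells, whose TIGIT
  marginal is 0.96, use (0.80, 0.96) — the default conditionals are
  infeasible at that marginal.
- **Encoded tonsil marginals.** TIGIT-expressing fractions: CD4 0.47
  (interfollicular baseline), 0.352 (Mz), 0.96 (Gcp/Gcc); CD8 0.53 and
  FOXP3 0.72 everywhere; plain CD3 T cells 0.667; NK 0.40; B, dendritic,
  macrophage and *other* cells 0. The Mz and CD3_T values are solved so
  that the pooled CD4 marginal is 0.47 and the pooled CD3⁺ marginal is
  0.52 under the preset's compartment composition (germinal centres
  B-cell-rich with a T-follicular-helper minority, T-zone CD4-rich —
  histologically realistic). Compartment sizes are 4000/2500/1500/2000
  (test) within the 800–6000 per-compartment range typical of digitally
  analysed regions, ~10,000 test cells total, plus a half-scale reference
  tonsil on the same slide.
- **Geometry.** Positions are uniform in the spot disc (4 mm
  microenvironment punches; 0.6 mm survey spots). Compartment labels are
  not spatially coherent — nothing downstream uses spatial structure.
- **Ground truth** (simulated cell type and checkpoint indicators) lives
  in a sidecar table so the pipeline cannot consume it by accident;
  recovery experiments use only the measurement table.

Scenario presets encode the qualitative contrasts of interest: Hashimoto
thyroiditis multiplies checkpoint brightness by 2.5 relative to the
comparable tonsil compartments; sarcoidosis is TIGIT-dominant (ratio > 1)
and brighter between granulomas than inside them; the other inflammatory
presets upregulate PD-1 more than TIGIT in lymphocyte-dense infiltrates
(ratio < 1); the tumour preset concentrates CD8 T cells at the invasive
margin with brighter checkpoints than the centre.

### What the generator does and does not emulate

It reproduces mixture-distributed intensities, compartment gradients,
correlated checkpoint positivity, and realistic compositions — enough to
exercise calibration, gating, normalization, coexpression, densities and
ANOVA end to end, and to show that the pipeline recovers encoded
population statistics through the full measurement chain. It does **not**
emulate segmentation errors, spectral bleed-through between channels,
spatial autocorrelation, staining batch effects, or inter-patient
variability beyond what different seeds provide. Passing recovery tests
therefore validates the analysis logic, not robustness to those imaging
artifacts.

## Validation workloads and problem sizes

The recovery experiments (`plexquant.recovery`) run the pipeline on the
tonsil preset (~15,000 cells including reference; a single run takes
about a second) and compare gated marginals against the encoded values at
3 binomial standard errors of the realized population size. The gradient
check requires RE[TIGIT] strictly increasing Ia < Mz < Gcp for all three
T subtypes across 10 consecutive seeds. Oracle suites use 1000 random
instances (threshold = brute-force max; ANOVA vs. sum-of-squares
decomposition) and a 2000-simulation null calibration of the ANOVA type-I
rate at α = 0.05 (accepted range 0.035–0.065). Unit-test cohorts are
smaller (1000–5000 cells) for speed.

## Known limitations

- The max-of-negatives cutoff is an order statistic: its sampling
  variability (and its ~1/(n+1) false-positive tail) is inherent to the
  rule; the package reports provenance (n and selector per marker) but
  does not second-guess the rule with mixture-model auto-thresholding,
  which is deliberately out of scope.
- Relative expression compares means of skewed distributions; with
  strongly different positive fractions between compartments, RE mixes
  "fraction expressing" with "brightness when expressing". The gated
  fractions are reported alongside for exactly that reason.
- Single-tissue ANOVA on per-cell values treats cells as independent,
  which ignores any within-compartment clustering; with patient cohorts,
  use per-patient units.
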