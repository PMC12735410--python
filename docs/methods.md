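# Methods

## The labeling model

Growth estimation assumes that over a short incubation (default 24 h) the
¹⁸O enrichment of extracted DNA above an unlabeled paired control reflects
DNA newly synthesized from soil water at the known label enrichment, and
that new DNA carries the oxygen mass fraction of average DNA. That fraction
is fixed at 31.21% (formula C₃₉H₄₄O₂₄N₁₅P₄); `dna_oxygen_fraction`
recomputes it from IUPAC 2021 atomic weights (C 12.011, H 1.008, O 15.999,
N 14.007, P 30.974), giving 31.198%, within 0.02 percentage points of the
conventional constant. DNA mass converts to biomass carbon through the
sample's MBC/DNA ratio (F_DNA), assuming extraction recovers biomass C and
DNA proportionally; no correction is applied for DNA extraction residue —
a known limitation of the method that would bias CUE, not something this
implementation can repair. CUE = G/(G+R) uses the respiration rate of the
same incubation unit; the pipeline accepts one rate per sample and leaves
labeled-versus-control vial pairing to the data preparer. A negative at%
excess (control above label) is instrument noise and is clamped to zero
with a logged warning rather than propagated as negative growth. When both
growth and respiration are zero, CUE is reported missing (NaN), never 0/0.

Units are fixed: µg for masses, g dry soil for soil normalization, hours
for incubation time; the turnover rate annualizes with 24 × 365 = 8760.

## Strategy scoring

Gene matching is exact-string on gene id; no fuzzy matching. Lability is
derived from the substrate class by fixed lists (labile: monosaccharides,
disaccharides, polysaccharides, hemicellulose, cellulose, amino sugars;
stable: lipids, chitin, lignin); an A-strategy gene with any other class is
an error, and S-strategy genes take no lability. Scores default to relative
abundance per sample (dividing by the sample's total table abundance)
because raw counts are sequencing-depth confounded. The bundled
`example_strategy_map` is illustrative only: it contains the five stable-C
genes highlighted in the afforestation literature (fabB, fabA → lipids;
hpaE, ACO, iorA → lignin) plus placeholder labile-C and S genes. Real
analyses require a curated user map; published A/S catalogs are not
reproduced here.

## Driver statistics

* **PC1 controls.** Variables are standardized before PCA (correlation-
  matrix PCA), since groups mix units (enzyme activities, gene scores,
  substrate fractions). PC1's sign is anchored positive on the variable
  with the largest loading magnitude, so scores are reproducible under
  column reordering.
* **Partial correlation** regresses both variables on the controls (with
  intercept) and correlates residuals; the p-value uses the t-distribution
  on n − 2 − k degrees of freedom. Controls are applied one group at a time
  by default (the fan layout of the correlation wheel); an all-controls
  mode exists but is not the default. Residual variance below 1e-12
  (relative) of the original is treated as a degenerate control.
* **Mantel test**: Pearson correlation of strictly-lower-triangle entries,
  one-sided (greater) permutation p with joint row/column relabeling of the
  second matrix, p = (1 + #{r_perm ≥ r_obs})/(B+1). The default distance is
  Euclidean on standardized variables; both choices are conventions, as no
  single canonical metric or sidedness exists for this screen, and both are
  configurable.
* **Importance screen**: a random forest (default 5000 trees, mtry = p/3)
  with out-of-bag permutation importance — for each tree, the OOB MSE
  increase when one feature is permuted within the OOB set, averaged over
  trees and expressed as a percentage of the mean OOB MSE (%IncMSE). Only
  ranks should be interpreted, not magnitudes.
* **Stage contrasts**: one-way ANOVA with Fisher's LSD pairwise tests on
  the pooled MSE and a compact-letter display (groups sharing a letter do
  not differ at α). LSD is used rather than Tukey deliberately, matching
  common practice in this literature.
* α = 0.05 throughout and **no multiple-testing correction** is applied
  across the screen — a deliberate mirroring of field practice and a stated
  limitation: the screen is exploratory, not confirmatory.

## Synthetic chronosequence

The generator emulates a five-stage space-for-time design (farmland FL and
plantation stands RP14/RP20/RP30/RP45, three plots each, n = 15). Defaults,
chosen once as field-realistic values:

| parameter | default | meaning |
|---|---|---|
| `cue_by_stage` | 0.25, 0.35, 0.45, 0.55, 0.65 | stage-mean CUE, monotone across the empirically reported 0.24–0.66 range; per-stage means are stand-ins, not claims |
| `noise_sd` | 0.06 | relative noise applied per quantity (CUE draws, lognormal respiration/MBC/DNA dispersion, covariates, IRMS enrichment reading) |
| `respiration_median` | 0.3 µg C g⁻¹ h⁻¹ | keeps growth and respiration the same order, with growth exceeding respiration in older stands |
| `soc_baseline`, `soc_cue_slope` | 2.0, 28.0 g C kg⁻¹ | SOC positively coupled to CUE |
| `effect_stable/labile/s` | +2.0 / +1.0 / −1.5 | signed gene-class couplings per unit CUE; stable-C carries twice the labile-C signal |
| `atpct_control` | 0.2 at% | natural ¹⁸O abundance |
| `o_total`, `t_hours`, `atpct_label_water` | 25 µg, 24 h, 20 at% | labeling setup |

Per sample: true CUE ~ truncated normal around its stage mean; respiration
log-normal; growth = CUE·R/(1−CUE) so the CUE identity holds exactly; the
labeling chain is then inverted to produce the at% enrichment the
instrument would read, with multiplicative measurement noise on that
reading. At `noise_sd = 0` the inversion is exact, making generator →
analysis round-trip recovery to 1e-9 relative error the primary
parameter-recovery property. Gene abundances sit on a relative-abundance
scale (per-sample totals ≤ 1): base value × (1 + effect · centered CUE)
plus noise, clipped at zero.

What the generator does **not** emulate: sequencing reads or assembly
artifacts, compositional closure of gene tables, spatial autocorrelation
between plots, non-Gaussian measurement error, and stage-dependent MBC or
enzyme kinetics. Passing tests therefore demonstrate correctness of the
calculation chain and calibration of the statistics under a clean
linear-Gaussian emulation — not that real afforestation data will show
these effect sizes.

## Numerical and design choices

* All stochastic routines take explicit seeds; the pipeline derives named
  per-stage substreams from a single run seed (stable spawn keys), so
  adding a stage never shifts another stage's draws, and reruns are
  byte-identical.
* Zero-variance variables are dropped (warning) before PCA; an all-constant
  group is an error.
* The Mantel p-count uses a 1e-15 tolerance when comparing permuted to
  observed statistics, so exact ties count as ≥.
* Per-row failures in CUE computation are recorded on the result row and
  logged; the pipeline never silently drops samples.
* Statistical calibration tests use the sizes 1000 null replicates
  (partial correlation, n = 15), 2000 replicates at 199 permutations
  (Mantel), and 2000 replicates (ANOVA); importance-rank tests use
  500-tree forests, large enough for stable ranks at n = 15 while keeping
  the suite fast.

## Known limitations

Desk-scale synthetic data cannot reproduce field numbers (the empirical
CUE–SOC R², per-stage means, or PC1 variance shares); those depend on
unpublished measurements. The partial-correlation screen assumes linear
relations and Gaussian-ish residuals; the LSD letters do not control the
family-wise error rate; and CUE estimates inherit all assumptions of the
¹⁸O method (no substrate-independent growth bias, proportional DNA
extraction, fixed DNA elemental composition).
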