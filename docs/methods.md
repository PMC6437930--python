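# Methods

This document records the generative model behind the synthetic data, the
statistical conventions used by the analysis stages, and the frozen scenarios
the test suite and the reproduction script run. Parameter defaults are listed
with the reason they were chosen.

## 1. Synthetic TMA core images (`tilquant.syndata.ImageSpec`)

Each core is a disk of tissue on a square canvas, scanned at a fixed pixel
scale, carrying circular cells that are rendered per channel.

| parameter | default | rationale |
| --- | --- | --- |
| `core_diameter_um` | 600 | standard 0.6 mm TMA punch |
| `um_per_px` | 0.3225 | common slide-scanner resolution at 20× |
| `cells_per_core_mean/sd` | 742 / 163 | cell counts typical of immune-enriched NSCLC cores |
| `leukocyte_fraction_mean/sd` | 0.40 / 0.25 | CD45⁺ fraction of cells, clipped normal per core — deliberately wide, so infiltration dominates between-core variance as it does in real cohorts |
| `cell_radius_range_um` | 3–6 | lymphocyte to large mononuclear cell radii |
| `marker_prevalence` | CD45 1.0, CD3 0.49, CD20 0.12, TIM-3/LAG-3/BTLA 0.25–0.30 | CD3/CD20 follow reported immune-infiltrate subset proportions (≈49% and 12% of leukocytes); checkpoint prevalences are mid-range defaults |
| `intensity_fg` / `intensity_bg` | (180, 20) / (20, 5) | ~9:1 signal-to-background, arbitrary units |
| `bleedthrough` | 0.02 | 2% spectral crosstalk between marker channels |
| `hole_*` | 0–3 holes of 10–40 µm radius | tissue folds/tears excluded from area |
| `gauss_sigma_px` | 1.0 | optical blur |
| `min_spacing_margin_um` | 1.5 | see below |

**Cell placement.** Cells are placed by dart throwing with a minimum centroid
spacing of `r_i + r_j + margin` — i.e. rendered disks never touch. This is
the package's own choice: it is what actually guarantees that, on noiseless
renders, connected components equal the planted cell count exactly, which is
the quantification oracle the tests rely on. (A looser spacing of one cell
radius lets disks merge and silently breaks count exactness.) Cells that
cannot be placed within 1000 tries are dropped; at default densities drops
are rare (<1% of cells).

**Positivity model.** Markers are expressed on leukocytes only. Marginal
prevalences are per-marker; co-expression is specified per combination,
either as

- a *scalar joint* `j`: a cell is all-member-positive with probability `j`,
  otherwise members are independent with the residual probability
  `(p − j)/(1 − j)`, preserving the marginals (note the realised pairwise
  joint is then `j + (1−j)·∏ residuals`, slightly above `j`); or
- a *fully specified 2³ table* for triples (`{"p111": t, "pair": q}`): all
  three pairwise joints equal `q` and the all-positive cell equals `t`.
  Feasibility of the eight cell probabilities is validated.

**Rendering.** Every positive cell paints a disk of intensity
N(180, 20) in its channels (all cells in DAPI), channels are Gaussian-blurred
(σ = 1 px), marker channels receive 2% bleed-through from each other marker,
and clipped-normal background N(20, 5) is added inside the tissue mask only
(holes and the area outside the core stay dark, which is what makes
DAPI-threshold ROI segmentation behave like real autofluorescent tissue).

**What the generator does not emulate:** nuclear/membrane subcellular
structure, cell shape anisotropy, uneven illumination, staining batch
effects, necrosis gradients, or spatial clustering of infiltrates beyond the
global leukocyte fraction. Detection performance numbers are therefore upper
bounds on real-image performance.

## 2. Synthetic cohorts (`tilquant.syndata.CohortSpec`)

Patients receive exponential survival times (Weibull when
`weibull_shape ≠ 1`) with hazard `baseline_hazard · ∏ HR_c` over the
patient's latent-positive combinations; latent status is Bernoulli
(`planted_prevalence` = 0.5). `baseline_hazard` = 0.0173/month gives a median
OS of ≈40 months. Censoring is the minimum of a 120-month administrative
horizon and an independent exponential (0.005/month), yielding ≈80% events.

Latent status also drives marker co-expression, so imaging noise attenuates
but does not destroy a planted effect:

- **Pure three-way interaction (default for planted triples).** Latent-
  positive patients get `p111` = `combo_joint_hi` (0.10), negative ones
  `combo_joint_lo` (0.01), with marginals and all pairwise joints identical
  (`combo_pair_joint` = 0.12). This was a deliberate design choice: under a
  scalar-joint mechanism every subset and superset of a planted triple
  carries the same prognostic signal, so "the planted triple ranks first in
  a duplex/triplex scan" is unattainable in principle — ranking among
  statistically equivalent combinations is noise. The three-way table makes
  the exact triple the only informative readout, which is the situation the
  scan is designed to detect.
- **Coexpression block (`marginal_boost` > 1, scalar joint).** Latent-
  positive patients double the member marginals and raise the scalar joint
  (0.25 vs 0.02); singles, pairs, the triple and PCA all see the block.

## 3. Quantification conventions (`tilquant.quantify`)

- **ROI**: largest 8-connected component of above-threshold tissue-channel
  pixels after morphological closing (disk radius 3 px); interior holes
  larger than 100 µm² stay excluded from the area, smaller ones are filled.
  Empty ROIs raise and the core is excluded with a warning in batch mode.
- **Labels**: 8-connected components of above-threshold pixels inside the
  ROI, size-gated at 20–400 µm² by default (5–400 µm² in the test panels, to
  keep the smallest clipped cells); optionally required to contain/touch a
  DAPI-label centroid.
- **Colocalization**: connected regions of the pixel-wise intersection of all
  member label images, kept when the region covers ≥ 50% of the smallest
  contributing member label (`min_overlap_frac`); a greedy centroid-distance
  alternative is provided.
- **Densities**: `count / tissue_area_mm²`, reported alongside
  `log10(density + 1)`; MFI is the mean intensity over label pixels.

Detection thresholds are per-channel operating parameters, as in real image
analysis. On default noise the background + bleed-through floor is ≈35 AU
against ≈180 AU foreground; the test panels use 60 AU.

## 4. Statistics conventions (`tilquant.stats`, `tilquant.cohort`)

- **Dichotomization**: hi strictly above mean+SEM, lo strictly below
  mean−SEM, mid-band excluded; SEM uses the sample SD (n−1). Group sizes
  therefore need not sum to the cohort size.
- **Log-rank (Mantel–Cox)**: implemented in-package over pooled risk sets
  because the reported hazard ratio is the O/E-ratio variant
  `(O₁/E₁)/(O₂/E₂)` with CI `exp(log HR ± 1.96·√(1/E₁ + 1/E₂))` — the number
  printed next to Kaplan–Meier panels by the common survival packages, which
  lifelines does not expose. lifelines' own log-rank is used as an
  independent cross-check in the tests, along with a brute-force risk-set
  enumeration written from the textbook definition.
- **Kaplan–Meier** and **Cox** (univariate, Efron ties, Wald CI) delegate to
  lifelines. The Cox oracle in the tests is a grid search of the Efron
  partial likelihood implemented independently.
- **Power**: Schoenfeld's event-count formula
  `Φ(|log HR|·√(d·p₁p₀) − z_{α/2}) + Φ(−|log HR|·√(d·p₁p₀) − z_{α/2})`
  cross-checked by Monte-Carlo simulation with the censoring horizon solved
  to hit the requested event fraction.
- **PCA coexpression groups**: PCA of column-standardised log values; a
  component's group is the markers with |loading| ≥ 50% of the component
  max; score signs are flipped so each score correlates positively with its
  members' mean expression.

## 5. Frozen scenarios (`tilquant.scenarios`)

All study conditions exercised by tests and the reproduction script are
frozen in one module so every consumer runs identical settings.

- **`triple_interaction_scenario`** (n = 400, HR = 0.5): pure three-way
  interaction on CD26/CD39/TIM-3 against the 12-marker ICP panel; the
  duplex/triplex scan covers all 286 combinations.
- **`coexpression_block_scenario`** (n = 400, HR = 0.5): correlated block on
  the same triple (marginals doubled, scalar joint 0.25 vs 0.02). The PCA
  group is built over the full block readout — the three singles plus the
  three pairwise and the triple co-label columns. With the wide (40 ± 25%)
  leukocyte-fraction variability, a shared infiltration factor dominates PC1
  of single-marker densities alone; including the colocalization readouts is
  the natural "full block" reading and was fixed before the acceptance test
  was frozen.
- **`null_scenario`** (n = 73): no planted effects; used for calibration.
- **`flagship_image_scenario`**: end-to-end image run at desk scale — 0.2 mm
  cores (cell count scaled with area to 82 ± 18), a 6-marker panel, 100
  patients × 3 cores, CD3-anchored planted triple at HR 0.3. A full cohort
  renders and re-quantifies from pixels in ≈75 s on one CPU via the
  streaming `simulate_and_quantify`.

Problem sizes in the tests (cohort counts, seed counts, replicate counts)
are the package's own choices, scaled to run the whole suite in well under
the CI budget on a single CPU while keeping every statistical band at ≥3σ
slack from its threshold.

## 6. Numerical choices and limitations

- Per-core combination counting at cohort scale uses a per-cell bitmask
  (≤62 markers) and one `bincount` per combination; cohort simulation is
  exact with respect to the image generator's positivity model but skips
  rendering and detection noise.
- Benjamini–Hochberg q-values use the step-up formula with the monotonicity
  clip `q ≥ p`.
- Survival-time ties are handled by grouping at equal times (log-rank,
  K-M) and Efron's method (Cox).
- p-values are floored at the smallest positive float to avoid log(0)
  downstream.
- The interactor stage is database-agnostic: it consumes tables, not live
  databases, so evidence/tissue vocabularies are whatever the upstream
  export provides (semicolon-separated tags).
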