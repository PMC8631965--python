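# Methods

## Overview

`hexgradient` quantifies two spatial properties of immunohistochemistry
(IHC) biomarkers in tissue sections, starting from per-cell coordinate
tables produced by any digital-image-analysis cell-detection step:

1. **Intratumoral heterogeneity (ITH)** of nuclear/membrane biomarker
   expression (ER, PR, Ki67, HER2 intensity class, HER2 membrane
   completeness), summarized by Haralick texture indicators of a hexagonal
   rank map and by Ashman's D bimodality.
2. **Immunogradient** of CD8+ cell infiltration across the tumor-stroma
   interface zone (IZ): per-aspect densities, the density center of mass
   (CM) and the immunodrop ratio.

Slide-level indicators feed a survival stack (optimal cutpoints,
Kaplan-Meier/log-rank, Cox proportional hazards with leave-one-out subset
selection) and the combined CD8 Immunogradient prognostic score.

## Hexagonal grids

Cells are assigned to regular hexagons by the nearest-center rule,
implemented as fractional axial coordinates plus cube rounding (these are
mathematically identical; the test suite checks agreement with brute-force
nearest-center search). Flat-top orientation and axial (q, r) indexing are
the defaults; boundary ties resolve deterministically through the rounding.

Two grids are used:

| grid | side | min cells/tile | purpose |
|---|---|---|---|
| coarse | 257 µm | 50 | ITH texture of marker percentages |
| fine | 65 µm | 5 | interface-zone extraction, CD8 densities |

Hexagons below the cell minimum are *insufficient sampling*: they stay in
the table (adjacency bookkeeping) but are excluded from ranking,
co-occurrence and density statistics. The coarse threshold counts all
cells, including background-class cells, by default (a switch restricts the
count to analyzable cells). The fine-grid minimum is lower because a 65 µm
tile holds roughly 16x fewer cells than a 257 µm tile.

Per-tile marker percentages use tumor-class cells as the denominator (IHC
scoring convention; configurable to all analyzable cells). HER2 positivity
means IHC intensity class 2+/3+; a tile with no HER2-scored cell is
undefined rather than 0% (CD8-stained slides carry no HER2 data at all).
HER2 membrane completeness (MC) is averaged over tumor cells and treated as
a percentage-scale value throughout, so MC texture uses the same 10-interval
ranking as the other markers.

Tissue-class areas used for slide-level CD8 density are approximated as
retained-tile area weighted by each tile's class cell fraction; pixel-level
compartment areas are not available from coordinate tables and this
approximation is documented as such.

## Texture indicators

Retained tiles' percentages are ranked into 10 fixed intervals: rank 1 is
[0, 10], rank k >= 2 is (10(k-1), 10k]. Tiles whose marker denominator
holds fewer than 10 cells are left unranked (percentages over near-empty
denominators are noise). A symmetric co-occurrence matrix P is tallied over
the 6-neighborhood of the tessellation — each unordered adjacent ranked pair
(a, b) increments P[a, b] and P[b, a] — and normalized to sum 1. Pairs with
an unranked member are dropped, not imputed, so P stays a proper
distribution. From P (indices i, j = 1..10):

- contrast = Σ P(i,j) (i−j)²
- dissimilarity = Σ P(i,j) |i−j|
- entropy = −Σ P(i,j) ln P(i,j), with 0·ln 0 = 0
- energy = Σ P(i,j)² (angular second moment)
- homogeneity = Σ P(i,j) / (1 + (i−j)²)

Dialect choices that differ across GLCM implementations are fixed and
documented here: natural-log entropy, energy without the square root, ranks
entering as integers 1..10. The 6-neighborhood is the hexagonal analog of a
unit-offset GLCM.

**Ashman's D.** Per-tile percentages are fitted with a two-component
Gaussian mixture (EM via scikit-learn: 10 k-means++ restarts, tolerance
1e-8 on log-likelihood, at most 500 iterations, SD floor 1e-3 percentage
points) and D = √2 |µ1−µ2| / √(σ1²+σ2²). D > 2 is the conventional
bimodality threshold. Fewer than 20 values flags the result unreliable;
identical values give D = 0 with a degenerate-fit flag. *Known limitation:*
with slide-level tile counts (tens of tiles), the unconstrained mixture can
isolate a narrow tail of a unimodal sample and report a large D; at the
calibration scale used in the tests (n = 2000) the estimator recovers the
analytic D of a planted mixture within 5% and stays below 2 on unimodal
controls.

## Interface zone and Immunogradient

On the fine grid, a tile is labeled tumor if its tumor fraction of
analyzable cells is >= 0.5 (ties break toward tumor — conservative toward
detecting an edge), stroma under the same rule, excluded otherwise or when
under-sampled. Rank 0 is the set of tumor tiles with at least one stroma
6-neighbor; breadth-first layers grow positive ranks into the tumor and
negative ranks into the stroma, to ±3 for the default 7-rank zone. Excluded
tiles block propagation. Defining the edge on the tumor side shifts aspect
membership by one rank relative to a boundary-centered convention; the
choice is fixed here and isolated so alternatives can be swapped.

Aspects: S = ranks −3..−1, TE = rank 0, T = ranks +1..+3. Per-rank and
per-aspect statistics are means and population SDs of per-tile CD8 density
(count / hexagon area); aspect statistics pool the aspect's tiles rather
than averaging rank means.

**Center of mass.** Every IZ tile is assigned to its nearest rank-0 tile
(hexagon-metric distance, which equals graph distance on the full lattice;
ties by Euclidean center distance, then smallest (q, r)). For each rank-0
tile whose group spans at least one negative and one positive rank with
positive total density, the local CM is Σ r·d_r / Σ d_r over the group's
per-rank mean densities; CD8_CM is the mean of local CMs and CD8_CM_sd
their population SD. CM is therefore in rank units (a normalized variant is
a configuration away), positive when infiltration shifts toward the tumor,
and invariant to scaling all densities. The local-profile construction is
one concrete definition of the CM variability indicator; it is isolated
behind a single function so other definitions can be substituted.

**Immunodrop.** CD8_ID = (d(−1) + ε) / (d(+1) + ε) with ε = 1 cell/mm²,
the smallest meaningful density unit, keeping the ratio defined on sparse
slides. Values > 1 mean an abrupt density drop from stroma into tumor
across the edge.

Because rank 0 sits on the tumor side, swapping tumor and stroma labels
shifts the zone by one tile; mirror antisymmetry of CM and reciprocity of
the immunodrop hold to about 0.05 on ramp profiles, exactly on flat ones.

## Survival stack

- **Kaplan-Meier / log-rank** are lifelines-backed; the k-sample statistic
  is used for 3+ groups. A fast vectorized two-sample log-rank (verified
  against lifelines to 1e-9) powers the cutpoint scan.
- **Optimal cutpoints** follow the minimum-p convention: candidates are
  midpoints of consecutive sorted unique values with both groups at least
  10% of the cohort; the returned p-value is *selection-biased* (no
  correction for the scan) and labeled as such. The good-prognosis
  direction is the group with higher KM survival at median follow-up. The
  suite demonstrates the selection bias on null data.
- **Cox models** use lifelines (Efron tie handling; Breslow is not
  implemented by the backend, and requesting it raises an explicit error).
  Hazard ratios are exp(coef) with 95% Wald intervals; the model
  likelihood-ratio statistic is reported.
- **Subset selection** enumerates covariate subsets up to size 5
  exhaustively (<= 15 candidates; greedy forward otherwise) and scores each
  by leave-one-out cross-validated concordance: each patient's risk is
  predicted by a model fitted without them (a compact Newton solver with
  Breslow ties, ridge-guarded against separation, handles the inner loop;
  the winning subset is refitted with the full Efron model). The selection
  criterion is pluggable; LOO concordance is the default reading of
  "leave-one-out cross-validation" for this purpose.
- **Combined CD8 score** sums 0/1 components for CD8_CM (high = 1),
  CD8_d_T (high = 1) and CD8_d_TE_sd (low = 1) at their cutpoints; strata
  are summarized by KM survival at exactly 60 months on the step function.

Clinical staging enters models dichotomized (pT1–2 vs pT3–4, pN0 vs pN1–3).
Model presets m1–m6 define variable pools: m1/m4 pathology + IHC + ITH
indicators (m4 adds FISH variables), m2/m5 add CD8 density and
Immunogradient indicators, m3/m6 pathology + CD8 indicators only.

## Synthetic virtual slides

The generator emulates the data structure the pipeline consumes; it does
not attempt biophysical realism (no tumor growth model, no stain or nucleus
simulation, no image rendering).

- **Geometry**: half-plane (exact signed distance), separated disks
  (exact), or thresholded smooth noise ("blob", distance transform on a
  4 µm raster, accurate to about the raster step).
- **Cells**: independent homogeneous Poisson processes per compartment,
  realized by thinning a full-extent process (exact). Default intensities
  1500–2000 cells/mm², representative of tumor cell densities in breast
  carcinoma sections.
- **Marker fields**: uniform (p), patchy (square patches with independent
  per-patch positivity ~ U(p_low, p_high)) and bimodal (per patch, p_high
  with the mixing probability, else p_low). Patch lattices are simple and
  analyzable, and modulate the Haralick indicators monotonically. Marker
  flags are drawn at *every* tumor cell, including CD8-carrying ones, so
  realized positivity matches the planted rate exactly in expectation.
- **CD8 field**: inhomogeneous Poisson with intensity g(signed distance):
  either plateau–linear transition–plateau, or piecewise-constant per
  hexagon-column band (used when the tumor-edge level must be controlled
  independently of the plateaus). Optional patchwise lognormal modulation
  everywhere, or mean-preserving two-point modulation {1−A, 1+A} of the
  edge band only.
- **Cohorts**: per-patient slides with one pseudo-random stream per slide
  derived from (master seed, patient index); survival times exponential
  with hazard h0·exp(β·z) on cohort-standardized *computed* indicators;
  censoring uniform over a window (12–120 months by default).
- **Score-ordered cohorts**: each patient gets a planted score in {1, 2, 3}
  (no zero stratum, matching the observed absence of triple-unfavorable
  patients in this setting); the three CD8 regimes are encoded in the
  band profile with a *fixed* tumor-edge level of 800 cells/mm² for every
  patient, so the Poisson noise floor of the edge-SD indicator is constant
  across the cohort and planted edge modulation (A = 0.9) is the only
  source of extra edge variance. Tumor plateau 800 vs 150 cells/mm² encodes
  the d_T regime; stroma plateau t/4 vs 2.5t encodes the CM regime.
  Per-score exponential hazards (0.0005, 0.0037, 0.0116 per month) put
  5-year survival near 97%/80%/50% for scores 3/2/1. The tumor-stroma
  boundary is aligned to a column midpoint of the fine grid so tile labels
  are unambiguous.

What passing tests on these fixtures do **not** show: robustness to
segmentation errors, irregular or fragmented tumor boundaries, tissue
folds/artifacts, non-Poisson cell clustering (e.g. lymphoid aggregates), or
inter-slide staining variation. The generator's Poisson placement also
means per-tile counts at 65 µm are small (~10–20 cells), so indicator noise
is realistic in magnitude but idealized in structure.

## Numerical choices and problem sizes

- Co-occurrence matrices are validated to sum to 1 within 1e-8 before
  Haralick summation; closed-form cases are reproduced to 1e-12.
- The LOO Newton solver clips steps (max component 5) and stops if |β|
  exceeds 30, so separation on dichotomized covariates degrades gracefully
  instead of overflowing; a 1e-9 ridge guards singular information
  matrices.
- Simulation-based checks use: 100 half-plane slides per gradient
  direction (1.2 x 1.2 mm, λ = 1500/mm²) for sign recovery; 100 seeds of
  n = 500 for Cox hazard-ratio recovery at HR 2.0 and 0.5; 500 label
  permutations for log-rank null calibration; 20 seeds of n = 300
  score-ordered cohorts for the combined-score stratification. These sizes
  give comfortable statistical margins for the stated thresholds while the
  whole suite remains desk-scale.
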