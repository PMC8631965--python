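# hexgradient

Hexagonal-grid spatial analytics for digital-pathology cell data:
intratumoral-heterogeneity (ITH) texture of biomarker expression,
tumor–stroma interface-zone CD8 Immunogradient indicators, and the
downstream survival stratification, including the combined CD8
Immunogradient prognostic score.

## Who this is for

Computational pathology groups that already run cell detection and tissue
classification on whole-slide images and want reproducible *spatial*
indicators from the resulting per-cell coordinate tables — one row per cell
with position (µm), tissue class (tumor/stroma/background), binary marker
positivity (ER, PR, Ki67, CD8), HER2 IHC intensity class and membrane
completeness. No image I/O is involved; the package starts where the
segmentation ends.

## What it computes

**ITH texture (coarse grid, 257 µm hexagons).** Cells are assigned to
hexagons by nearest center; hexagons with fewer than 50 cells are excluded
as insufficient sampling. Per-hexagon marker percentages are ranked into 10
intervals (0–10%, >10–20%, …, >90–100%), a symmetric co-occurrence matrix
P is tallied over adjacent hexagon pairs, and five Haralick indicators
summarize it:

    contrast      = Σ P(i,j)(i−j)²        dissimilarity = Σ P(i,j)|i−j|
    entropy       = −Σ P(i,j) ln P(i,j)   energy        = Σ P(i,j)²
    homogeneity   = Σ P(i,j)/(1+(i−j)²)

Bimodality of the per-hexagon distribution is measured by Ashman's
D = √2·|µ₁−µ₂|/√(σ₁²+σ₂²) from a two-component Gaussian mixture (D > 2
conventionally indicates bimodality).

**Immunogradient (fine grid, 65 µm hexagons).** Tiles are labeled
tumor/stroma by majority cell class; the interface zone (IZ) spans seven
signed ranks −3…+3 around the tumor edge (rank 0 = tumor tiles touching
stroma), grouped into stroma (S), tumor edge (TE) and tumor (T) aspects.
From per-tile CD8 densities the package computes per-aspect means and SDs
(CD8_d_S, CD8_d_TE, CD8_d_T, …), the density center of mass
CM = Σ r·d_r / Σ d_r (positive = infiltration shifted toward the tumor) with
its variability CM_sd over local profiles, and the immunodrop
ID = (d₋₁+ε)/(d₊₁+ε), the density ratio across the tumor edge.

**Survival stack.** Optimal cutpoints by the minimum-p log-rank scan
(reported p-values are selection-biased and labeled as such), Kaplan–Meier
and log-rank tests, univariate and multivariate Cox proportional-hazards
models with leave-one-out subset selection, and the combined CD8
Immunogradient prognostic score: one point each for favorable CD8_CM
(high), CD8_d_T (high) and CD8_d_TE_sd (low), with per-stratum 5-year
(60-month) KM survival.

**Synthetic virtual slides.** A first-class generator plants tumor/stroma
geometry, Poisson cell placement, structured marker fields (uniform /
patchy / bimodal), CD8 gradients across the boundary, and cohorts whose
survival follows a proportional-hazards model on the *computed* indicators
— every fixture ships its ground truth, so all tests check recovery of
known quantities.

## Worked example

```python
from hexgradient.synthetic import (SlideSimConfig, MarkerField,
                                   CD8GradientSpec, simulate_slide)
from hexgradient.pipeline import RunConfig, run_slide

cfg = SlideSimConfig(
    extent_mm=(2.0, 2.0),
    markers={"ER": MarkerField(kind="bimodal", p_low=0.15, p_high=0.85,
                               mixing=0.5, patch_mm=0.6)},
    her2=MarkerField(kind="uniform", p=0.5),
    cd8=CD8GradientSpec(stroma_density=200.0, tumor_density=800.0,
                        transition_um=300.0),
    seed=42,
)
cells, truth = simulate_slide(cfg)           # 9091 cells
record = run_slide(RunConfig(), cells)
for k in ("ER_pct", "HER2_pct", "ER_entropy", "ER_AshD",
          "CD8_d_S", "CD8_d_T", "CD8_CM", "CD8_ID"):
    print(f"{k}: {record[k]:.3f}")
```

prints

```
ER_pct: 46.640
HER2_pct: 50.232
ER_entropy: 3.079
ER_AshD: 7.195
CD8_d_S: 224.377
CD8_d_T: 717.210
CD8_CM: 0.919
CD8_ID: 0.490
```

Reading the output: the bimodal ER field (patches at 15% vs 85% positivity,
mixed evenly) lands near 47% overall but with high spatial rank entropy
(3.08) and Ashman's D well above the bimodality threshold of 2. The planted
CD8 gradient rises from 200 cells/mm² in stroma to 800 in tumor: the
measured aspect densities recover the plateaus, the center of mass is
positive (infiltration shifted toward the tumor), and the immunodrop is
below 1 (density *increases* across the edge), consistent with the planted
direction.

A command-line surface wraps the same library for shell use:

```sh
hexgradient simulate --out fixtures --seed 0
hexgradient immunogradient --cells fixtures/halfplane_gradient_up/cells.csv
hexgradient survival --cohort cohort.csv --indicators indicators.csv --model m3
```

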