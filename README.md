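# immunohex

Spatial profiling of CD8+ cytotoxic T lymphocytes at the tumor/stroma
interface of hepatocellular carcinoma (HCC) resections, and survival
modeling of post-resection recurrence risk.

The package is aimed at digital-pathology and biostatistics groups who have
(a) whole-slide tissue segmentations (epithelium / stroma / background),
(b) cell-detection tables with phenotype calls, and (c) clinical follow-up,
and who want to quantify *where* the cytotoxic infiltrate sits relative to
the invasive edge — not just how dense it is — and feed those indicators
into recurrence-free-survival (RFS) models. A full synthetic-data module
generates segmentation scenes, inhomogeneous-Poisson CD8+ point patterns
and proportional-hazards cohorts, so the entire pipeline runs and is tested
without any slide data.

## Method

**Hexagonal interface zones.** The slide is tessellated by a flat-top
hexagonal grid of side *s* = 65 µm (hexagon area (3√3/2)·s² ≈ 10 977 µm²).
Per hexagon, tissue-class areas and CD8+ counts are aggregated. Hexagons
are labeled epithelial or stromal by area majority; epithelial hexagons
with a stromal 6-neighbor form the extracted epithelial edge (**rank 0**).
Breadth-first layers over the hexagon graph assign rank +*k* to epithelium
*k* steps inside the edge and −*k* to stroma *k* steps outside. Tumor and
non-malignant liver compartments are ranked independently. From the
five-zone window *k* ∈ {−2, …, +2}, four indicators are computed per
compartment (densities in cells/mm² of tissue area):

| indicator | definition |
|---|---|
| mean density | Σ counts / Σ tissue area over the window |
| edge SD | sample SD of per-hexagon density at rank 0 |
| center of mass | Σ k·D(k) / Σ D(k), D(k) = rank-k mean density |
| immunodrop ratio | D(−1) / D(+1) |

Low edge SD — a uniform, possibly exhausted infiltrate with no dense
lymphoid aggregates — flags poor prognosis.

**Survival modeling.** Univariate Cox screening of clinicopathologic and
indicator covariates; forward stepwise multivariate Cox with
likelihood-ratio entry/stay tests (α = 0.05, Breslow ties); Kaplan–Meier +
log-rank on dichotomized predictors; Fisher's exact test on the
recurrence × margin table. The two independent adverse predictors — R1
resection margin and low edge SD (< 5.8, configurable) — sum to a
**Relapse Score** ∈ {0, 1, 2}, stratified through the pre-registered
contrasts {0} vs {1, 2} and {0, 1} vs {2}.

## Worked example

```python
from immunohex import (SceneParams, Cd8ProfileParams, generate_scene,
                       generate_cd8_points, CD8InterfaceModel)

scene = generate_scene(SceneParams(seed=1))           # 4×4 mm, tumor r=1.2 mm
cells = generate_cd8_points(scene, Cd8ProfileParams(seed=2))
res = CD8InterfaceModel(scene, cells).fit()
print(res.summary().round(3).to_string(index=False))
```

```
compartment  mean_density  edge_sd  center_of_mass  immunodrop_ratio  log_mean_density  log_edge_sd  log_immunodrop_ratio
      tumor       501.428  297.423          -0.516             2.827             6.219        5.699                 1.039
      liver       326.601  165.951          -0.128             1.203             5.792        5.118                 0.184
```

The default generator places a CD8+ density peak on the stromal side of the
tumor edge with a 0.3× drop inside the epithelium: the tumor immunodrop
ratio ≈ 2.8 (density falls almost 3-fold crossing the edge inward), the
center of mass ≈ −0.5 (infiltrate weighted to the stromal side), and the
edge SD ≈ 300 cells/mm² reflects Poisson plus edge-profile variability at
rank 0. The liver interface, generated without an inside drop, shows a
ratio near 1 (≈ 1.2) and a center of mass near 0 (≈ −0.1).

The survival half mirrors statsmodels:

```python
from immunohex import CohortParams, generate_cohort, RecurrenceModel

cohort = generate_cohort(CohortParams(n_patients=2000, seed=5))
fit = RecurrenceModel(cohort).fit()
print(fit.summary().round(3).to_string(index=False))
```

```
covariate  estimate    se  chi_square  p_value  hazard_ratio  hr_ci_low  hr_ci_high
       r1     1.932 0.066     853.253      0.0         6.904      6.065       7.860
   low_sd     1.386 0.054     668.602      0.0         4.001      3.601       4.444
```

Both generating effects (hazard ratio 7.162 for R1, 4.065 for the low-SD
flag) are recovered within sampling error and both survive the stepwise
LR selection.

A command-line pipeline chains everything on synthetic data:

```bash
immunohex run-all --seed 7 --out run7     # simulate → hexify → rank → indicators → survival
immunohex survival --cohort run7/cohort.csv --sd-cutoff 5.8 --ties breslow --out run7
```

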