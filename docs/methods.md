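# Methods

## The spatial model

The object of analysis is the five-hexagon-wide interface zone straddling
the epithelial edge of a tumor. The pipeline makes three modeling
commitments:

1. **Subsampling unit.** A flat-top hexagonal grid of side 65 µm (area
   ≈ 10 977 µm²), axial (q, r) addressing, origin at the lower-left corner
   of the slide bounding box. Orientation is a free choice — nothing
   downstream depends on it because only rank-derived quantities are
   reported — but it is fixed and recorded in output metadata so absolute
   indices are reproducible within this implementation. Pixels and cells
   are assigned to the hexagon with the nearest center (exact partition;
   boundary ties break to the lexicographically smallest (q, r)). Pixel
   assignment is by pixel-center location, so no pixel is split and areas
   are conserved to machine precision.

2. **Edge and ranks.** A hexagon is *epithelial* when epithelium occupies
   ≥ 50% of its tissue (epithelium + stroma) area, *excluded* when tissue
   covers < 50% of its total area or it lies in no annotated compartment.
   Rank 0 is an epithelial hexagon with ≥ 1 stromal 6-neighbor — the
   epithelial side owns the edge. Signed ranks are breadth-first graph
   distances from the rank-0 set: +k into epithelium, −k into stroma.
   Excluded hexagons never form edges and are not traversed, so tissue
   tears and vessels do not generate spurious deep ranks; an optional
   `edge_through_excluded` flag lets the edge test look one step past a
   single excluded hexagon for gap-ridden segmentations (off by default).
   Tumor and non-malignant liver are ranked in separate passes with the
   other compartment treated as absent, yielding independent interface
   profiles.

3. **Indicators.** Per-hexagon CD8+ density uses tissue area
   (epithelium + stroma) as the denominator — background must not dilute
   density. Rank means are area-weighted (total count / total area). The
   four indicators over the window k ∈ {−2…+2}: zone mean density; edge SD
   (sample SD, n−1, of rank-0 per-hexagon densities; undefined below two
   rank-0 hexagons); center of mass Σ k·D(k)/Σ D(k) (undefined for an
   all-zero profile); immunodrop ratio D(−1)/D(+1) (undefined, not
   infinite, when D(+1) = 0). Undefined indicators propagate as missing
   values, never as errors. Log copies use ln(x+1) for quantities that can
   be zero (densities, SD) and plain ln for the ratio; both raw and log
   values are always emitted because the conventional 5.8 dichotomization
   cutoff for the edge SD has no unambiguous scale — the default applies it
   to the raw SD and the reports flag that choice.

## The survival model

Cox proportional hazards on RFS with Breslow tie handling by default
(Efron selectable); Wald 95% CIs (exp(β ± 1.96·SE)); model LR χ² against
the null partial likelihood. Numerical maximization is delegated to
statsmodels' `PHReg` (convergence at relative log-likelihood change
< 1e−9 within 100 iterations); monotone likelihood (perfect separation) is
detected from diverging estimates/SEs and returned as a flagged
non-convergent fit. Variable selection is forward stepwise by 1-df LR
tests with backward re-checking, α = 0.05 to enter and to stay, after a
univariate Cox screen (p < 0.05); the selection path is recorded. At this
α, forward selection over m pure-noise candidates admits one with
probability ≈ 1 − 0.95^m; the false-selection simulations in the test
suite bound exactly that rate rather than pretending selection is
error-free.

Fisher's exact test is two-sided by the minimum-likelihood rule (sum of
hypergeometric probabilities ≤ that of the observed table); the odds ratio
is ad/bc, flagged undefined when bc = 0. The Relapse Score sums two binary
adverse flags — R1 margin and low edge SD (< cutoff, default 5.8, never
re-estimated from the data to avoid optimal-cutpoint circularity) — and is
stratified only through the two pre-registered contrasts {0} vs {1,2} and
{0,1} vs {2}.

## The synthetic-data generators

**Scene.** A rough-edged disc of tumor epithelium (radius perturbed by a
smooth 5-harmonic angular noise of relative amplitude
`tumor_boundary_roughness`) centered in the domain, a stromal band of
fixed width around it, liver epithelium outside, and a 65 µm background
frame at the slide border (compartment: excluded). The band is split
midway between the tumor and liver compartments so each compartment pass
owns one side of its epithelial/stromal interface; a pixel can carry only
one compartment label, and this split mirrors how pathologist annotations
partition peritumoral stroma. Defaults: 4 × 4 mm domain, 2 µm/pixel,
1.2 mm tumor radius, 400 µm band (≈ 3.5 hexagon widths, enough for the
−2…+2 window on both sides of each edge).

**CD8+ points.** An inhomogeneous Poisson process realized by thinning.
Intensity at signed edge distance d (positive = tumor-epithelial side,
negative = stromal/liver side, measured from the epithelium/stroma class
boundary of the tumor compartment, not the compartment outline):

    λ(d) = base · [ (1 if d < 0 else inside_drop) + peak · exp(−|d|/decay) ]

Defaults: base 300/mm², peak multiplier 3, decay 100 µm, inside drop 0.3 —
a peritumoral density peak with a roughly 3-fold drop crossing into the
epithelium, the asymmetry the immunodrop ratio detects. The defaults are
chosen for statistical power (hundreds of cells per interface zone), not
calibrated to any particular cohort's absolute densities, which are not
published per slide. An optional Neyman–Scott component (parent rate,
Poisson cluster size, Gaussian σ 40 µm) emulates lymphoid-aggregate
clustering; its children falling on background are dropped, not resampled,
preserving the thinning interpretation. Cluster structure raises the
per-hexagon dispersion index above 1 and inflates the edge SD — the
mechanism by which TLS-like structure maps onto the high-SD/good-prognosis
pole of the indicator.

**Cohorts.** Exponential event times (constant baseline hazard — the
simplest model satisfying proportional hazards exactly) with log-hazard
linear in two independent Bernoulli flags, administratively censored.
Defaults emulate the reference cohort: n = 41, P(R1) = 8/41, baseline
hazard 1/900 days, censoring at 2000 days. Both flags are adverse:
R1 multiplies the hazard by 7.162 and the low-SD state by 1/0.246 ≈ 4.065.
The low-SD coefficient is the reciprocal of the published protective
hazard ratio of the SD covariate itself, so a Cox fit on
(R1, high-SD = 1 − low-SD) recovers hazard ratios 7.162 and 0.246; this
orientation also makes the Relapse Score monotone in risk (median RFS
ordered score 0 > 1 > 2), which the protective-low-SD orientation would
violate.

### What the generators do not emulate

Real slides have anisotropic, multi-focal tumors, intratumoral stroma,
necrosis, staining artifacts, and cell-detection error (false
positives/negatives, merged nuclei); the generator has none of these. The
synthetic tumor edge is a single closed curve, so rank-0 sets form one
ring; fragmented invasion fronts are exercised only by the random-label
property tests. Passing tests therefore demonstrate correctness of the
geometry, ranking, indicator arithmetic and statistical machinery under
the stated point-process and hazard models — not robustness to
segmentation or detection noise in clinical material.

## Numerical choices and degenerate inputs

- Hexagon assignment uses cube rounding plus a 6-neighbor nearest-center
  refinement with tolerance 1e−9·s² for tie detection.
- Per-hexagon class-area quantization error is bounded by a half-pixel
  band along the boundary (≈ perimeter·pixel/2); halving the default 2 µm
  pitch moves interior per-hexagon areas by < 2% of the hexagon area.
- Zero-tissue hexagons are excluded from density lists; a compartment with
  no hexagons in the five-rank window yields missing indicators (a slide
  without liver parenchyma still reports tumor indicators).
- Cox fits reject constant covariates and event-free cohorts with explicit
  errors; stepwise selection returns an explained null model when no
  candidate passes the screen.
- All generators are deterministic under their seed; the pipeline manifest
  records the seed, a config hash and per-file SHA-256 digests, and a
  rerun with the same config reproduces every numeric output byte-for-byte.

## Problem sizes

The shipped defaults (4 × 4 mm scene at 2 µm/pixel, ~1 500 hexagons,
~5 000 cells; cohorts of 41–2 000 patients) run the full pipeline in
seconds on one CPU. The test suite uses a 2.4 × 2.4 mm scene for
multi-seed point-process statistics and n = 500–2 000 cohorts for
selection-consistency and effect-recovery simulations; these sizes give
the power the assertions need while keeping a full run to a few minutes.

## Known limitations

- Ranks are graph distances, not Euclidean geodesics; a rank step equals
  one hexagon pitch (~112.6 µm across flats), so zone widths scale with
  the grid side.
- The edge rule (epithelial hexagon with stromal neighbor) and the
  excluded-hexagon adjacency convention are fixed choices among several
  defensible ones; both are config-exposed.
- The 5.8 edge-SD cutoff is a configuration default carried over from
  prior practice, not re-derived; its scale (raw vs log) is ambiguous in
  the source literature and is flagged in every report.
- Absolute hexagon indices are implementation-defined (origin/orientation
  convention); only rank-derived indicators are comparable across
  implementations.
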