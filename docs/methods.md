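# Methods

This note documents the models, algorithms, defaults, and numerical choices
behind each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Synthetic four-way cross

Meiosis is simulated per parental gamete as a two-state Markov chain along
each linkage group. The maternal gamete carries allele A or B, the paternal
gamete C or D; a progeny's genotype class at a marker is the pair. Between
adjacent markers `d` cM apart the switch probability is the Haldane map
function `r = (1 − e^(−2d/100))/2`. Haldane (no crossover interference) is
used because it is the standard closed-form default; chi-square-style
interference would narrow genotype-probability intervals slightly but change
no downstream contract.

Phenotypes mirror the across-year mixed model used for estimation:

    y = μ + year + Σ QTL contrasts + polygenic + GxY + row + col + spatial + ε

- QTL contrast effects are ±e/2 per carried allele (maternal contrast for
  A vs B, paternal for C vs D, interaction for the coupling classes AC/BD vs
  AD/BC), attached at the map marker nearest the stated position.
- The polygenic term is iid `N(0, σ²_a)` per genotype, shared across years;
  GxY is redrawn per year; `ε` is per upright.
- The spatial surface is a low-order 2-D polynomial (linear + cross term)
  plus two sinusoids in the row/column coordinates, standardized and scaled
  by `spatial_amplitude`. It deliberately contains both straight-line
  variation (absorbable by row/column terms) and curvature (only the spline
  term can absorb it), so AIC model selection has a real decision to make.
- Every realized component is emitted in a sidecar truth table whose columns
  sum exactly to the observation — parameter-recovery tests diff against it.

The generator does **not** simulate genotyping error, missing calls,
segregation distortion, selective sampling, or trait-specific measurement
error distributions. Passing tests therefore demonstrate correctness of the
estimation machinery under a clean generative model, not robustness to the
artifacts of real genotyping-by-sequencing data.

Default study conditions used by the examples and verification runs: maps of
3–5 linkage groups × 11 markers × 100 cM (a desk-scale stand-in for the
1560-marker composite map, which the map simulator can also produce),
populations of 120–168 progeny matching the larger real population, 3 years,
10 uprights per genotype.

## Shape chimeras

Templates for the five berry-shape classes (round, oblate, oval, pyriform,
spindle) are parametric radial silhouettes `r(θ) = ellipse(r_x, r_y)·(1 +
taper·sin θ)` rasterized at 256×256 (radii scale with raster size). The
published evaluator reference images are not available; these are synthetic
stand-ins that reproduce each class's aspect ratio and axial asymmetry, and
any user-supplied binary raster can replace them.

**Normalization** brings every silhouette to a common centroid and area
(default 12 000 px at 256×256): largest 4-connected component, hole fill,
bilinear rescale by the areal factor, re-threshold at 0.5, then an exact-area
adjustment that grows or peels the boundary in taxicab-distance bands
(band-k pixels are always 4-adjacent to band-(k−1), so growth preserves
4-connectivity; peeling removes only *simple* pixels — a local union-find
test on the 8-neighborhood — so necks are never severed and no hole opens).
Within the partially used band, pixels are taken in golden-angle order around
the centroid so the adjustment is rotationally even. Finally an integer shift
centers the centroid to within half a pixel.

**Chimera synthesis.** The differential distance transform is
`DDT = EDT(img) − EDT(~img)`, strictly positive on foreground and strictly
negative on background. Per genotype-year, the DDTs of the (typically ten)
per-upright template images are summed and thresholded at zero (ties to
background). Summation makes the single-shape case exactly idempotent — the
chimera of N copies of one template is that template, pixel for pixel — and
the mixed case a majority-like blend whose boundary is the zero crossing of
the summed signed distances.

**Descriptors.** UKEC and UKLvW come from the second-central-moment fitted
ellipse (eccentricity `√(1 − b²/a²)`; a degenerate minor axis returns the
sentinel UKEC = 1 with a flag). UKSO is area over convex-hull area. UKTO
resamples the outer contour into m = 64 equal-arc-length segments and sums
the absolute slope changes between consecutive segments, normalized by π —
any convex contour scores 2 (one full turn); waviness adds. m is configurable
because the slope-chain-code literature fixes no canonical value; 64 keeps
segment length ≈ 6 px on the default raster, below which rasterization
jitter dominates. UKUX/UKUY count the horizontal and vertical unit moves of
the 4-connected crack boundary (a crack between vertically adjacent differing
pixels is traversed horizontally, and vice versa), reported as log₁₀; for an
axis-aligned w×h rectangle these are exactly log₁₀(2w) and log₁₀(2h), and
`10^UKUX + 10^UKUY` is always the total boundary length. Eccentricity near 0
is ill-conditioned: single-pixel rasterization differences move UKEC of a
near-circle by ~0.1, so comparisons of near-round shapes should use UKLvW.

## Trait curation

Curation order per trait is fixed: rot-flagged rows out first; then the
regression-outlier test — ordinary least squares of the trait on population,
genotype and year (treatment-coded), externally studentized residuals
computed in closed form from leverages, the single worst observation removed
when its Bonferroni-adjusted two-sided p is below α = 0.05, iterated to
convergence; then a hard cut at 3 standard deviations from the trait mean.
The iterated-worst-case protocol mirrors the classical single-outlier test
applied repeatedly; re-running the full trim on its own output is a fixed
point. A rank-deficient model falls back to the SD step alone, logged.
Zero-variance traits pass untouched.

Analysis units are means over available uprights per genotype-year (counts
retained). Pearson correlations are computed on the genotype × trait matrix
within each year and averaged across years; if finer replicate time levels
exist within a year they are averaged the same way (the real data's
month-level structure is not otherwise specified). p-values use the t
statistic of the averaged correlation at the mean per-year sample size —
a pragmatic choice; treat them as descriptive. Trait clusters come from
complete-linkage agglomerative clustering on `1 − |r̄|` cut at 0.6:
complete linkage guarantees every within-cluster pair has `|r̄| ≥ 0.4`,
matching the "cliques of traits" reading; only non-singleton clusters are
reported. Both the distance and the cut height are configurable.

## Mixed models, BLUPs, heritability

The additive genomic relationship matrix is VanRaden method 1,
`A = WW′ / (2Σ p_k(1−p_k))` on column-centered 0/1/2 dosages; monomorphic
(zero-variance) markers are dropped with a warning. For synthetic four-way
classes, dosages count the reference maternal and paternal alleles
(A and C), giving a biallelic coding consistent with the cross structure.

REML maximizes the restricted log-likelihood
`ℓ = −½(log|V| + log|X′V⁻¹X| + y′Py)` over non-negative variance components
with L-BFGS-B (analytic gradients `∂(−2ℓ)/∂σ²_k = tr(PV_k) − y′PV_kPy`,
bounds at zero, residual floored at 1e−10 in standardized units, ftol 1e−12,
max 200 iterations). The response is standardized internally so components
are optimized in units of var(y) — this keeps traits of any scale (chimera
solidity has variance ~1e−5) equally well conditioned — and the
log-likelihood is corrected back to the original scale. With a single
non-residual term the likelihood is evaluated in the eigenbasis of ZKZ′,
making each evaluation O(np²) instead of O(n³). Non-convergence flags the
result; it is never silent. BLUPs and their prediction-error variances come
from `û = σ²KZ′Py` at the optimum.

Model selection enumerates all subsets of {row, column, spline} with the
genotype term forced in, and keeps the lowest AIC (`−2ℓ_REML + 2k` with
k = fixed effects + variance components; ties go to the smaller model). The
spline term is a tensor-product cubic B-spline basis over the plot (row,
column) coordinates with iid coefficient variance; basis dimension defaults
to 6×6 (4×4 in the small demo). This is one reasonable parameterization of a
2-D smooth; equivalence with any specific spline implementation is
approximate by construction.

The across-year model adds a fixed year effect and a GxY term, retained only
if the LRT against the ½χ²₀ + ½χ²₁ boundary mixture has p < 0.05. Note: on
genotype-year means with one record per genotype-year, GxY and residual are
confounded (Δℓ = 0, GxY dropped) — the gate is informative only when
within-genotype-year replication survives to the model, as in the unit tests.

Heritabilities are the variance ratios given above. The pipeline also tests
each model's genotype variance against the same boundary mixture and scans
only traits × models with p < 0.05; without this gate, BLUPs of heritability-
free traits — which are low-variance linear images of the marker-built A
matrix — produce spuriously marker-aligned scan signals.

## QTL scanning

Genotype-class probabilities at markers and pseudomarkers (default grid step
1 cM; 2 cM in the examples for speed) condition each gamete on its nearest
informative flanking markers: `P(g|L,R) ∝ t(L→g)·t(g→R)` with Haldane
transitions, one-flank fallback at chromosome ends, prior ½ with no
information, and exact point mass at typed markers. Class probabilities are
products of the two independent gamete probabilities. No genotyping-error
parameter is modeled.

The Haley–Knott scan regresses the BLUP vector on [1, x_m, x_p, x_i], the
expected contrast values at each grid position, with
`LOD = (n/2)log₁₀(RSS₀/RSS₁)` via per-position orthonormal bases (rank-
deficient, uninformative positions degrade gracefully to LOD 0). Permutation
thresholds shuffle the BLUP vector across genotypes, n_perm = 1000 by
default, and take the stated percentile of the genome-wide maximum LOD; the
permutation LODs are computed for all permutations simultaneously by matrix
projection, which is what makes 1000-permutation thresholds cheap enough to
use inside simulation studies. 1.5-LOD support intervals take the outermost
grid positions on the peak's linkage group within 1.5 LOD of the peak (peak
ties go leftmost). Effects are contrast sums of the four class means fitted
at the peak (undefined, flagged NaN, if a class is empty); marker R² is
`1 − 10^(−2·LOD/n)`.

The stepwise search is a simplified, additive-only mirror of the full
forward/backward penalized-LOD procedure: forward addition of the position
that most improves `pLOD = LOD − penalty·(#QTL)` (penalty = the
95th-percentile permutation threshold), backward pruning while it helps, at
most 6 QTL; per-QTL intervals and effects come from profile curves with the
other QTL fixed. Interaction terms and two-dimensional-scan-derived penalty
pairs are out of scope; they multiply runtime without touching the meta-QTL
interface, which consumes only additive hits.

Because scans run on BLUPs, peaks can shift a few cM from the causal position
(shrinkage toward genomic relatives redistributes signal along the
chromosome); the 1.5-LOD intervals absorb this at realistic effect sizes, as
the recovery tests verify (coverage ≥ 90% at 20% PVE, n = 168).

## Meta-QTL

Intervals are closed; touching endpoints count as overlap (configurable).
Maximal cliques are enumerated exactly — per linkage group these graphs are
interval graphs, so enumeration is cheap at any realistic size — and the
engine is verified against exhaustive subset search. Extents intersect
(max-lo, min-hi), guaranteed non-empty by the Helly property of 1-D
intervals; the position is exactly the midpoint, rounded half-away-from-zero
to 0.1 cM only in reports. Within-trait "stable" meta-QTL require at least 3
of the 4 models (three years + all-years) and mean marker R² ≥ 0.10,
boundary inclusive. Trait groups (synonym sets across studies) are declared
in YAML, never inferred; group filters over {mean R², model/trait/population/
study/method counts} are AND-combined with a pass/fail log per candidate.

## Problem sizes and runtime

The verification suite uses desk-scale sizes chosen as the package's own
defaults: maps of 3–5 groups × 6–11 markers, 120–168 progeny, 100 recovery
simulations with 1000-permutation thresholds, 200 REML recoveries at n = 500,
2000 null-calibration replicates. The full test suite runs in under a minute
on one CPU; `scripts/acceptance.py` in about 40 s; the demo pipeline in about
30 s.

## Limitations

- Shape templates are approximations; absolute descriptor values depend on
  raster resolution and template geometry, so cross-dataset comparisons
  should renormalize.
- The correlation p-values and the month-averaging rule are pragmatic
  resolutions of underspecified details, documented above.
- The stepwise search is additive-only; epistatic architectures will be
  reported as their marginal additive projections.
- Scanning BLUPs (by design, matching the estimation chain this package
  mirrors) trades a small peak-location bias for noise suppression; raw
  genotype means can be passed to the scan functions directly when that
  trade is not wanted.
- REML uses dense linear algebra: comfortable to a few thousand observations,
  not engineered for biobank scale.
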