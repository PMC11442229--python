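# cranqtl

Meta-QTL analysis for outbred four-way crosses, built around the computational
chain of cranberry (*Vaccinium macrocarpon*) fruit-quality genetics: berry-shape
chimera imaging, genomic-BLUP heritability estimation, Haley–Knott QTL scanning,
and interval-overlap meta-QTL synthesis. A synthetic-data generator with known
ground truth replaces field data, so the whole pipeline is verifiable offline.

## Who this is for

Breeding-genetics analysts working with heterozygous outbred crosses
(progeny genotype classes AC/AD/BC/BD from maternal alleles A/B and paternal
alleles C/D) who want to go from multi-year, spatially structured field
phenotypes to consensus genomic regions ("meta-QTL") that are stable across
years, traits, populations, or studies — and methods developers who need a
tested, seedable reference implementation of each stage.

## What it computes

**Berry-shape chimeras.** Categorical shape scores are replaced by canonical
binary silhouettes, normalized to a common centroid and area, and fused per
genotype-year by summing differential distance transforms
(`DDT = EDT(img) − EDT(~img)`, positive exactly on foreground) and thresholding
at zero. Six descriptors quantify the chimera: moment-ellipse eccentricity
(UKEC), length:width ratio (UKLvW), slope-chain-code tortuosity (UKTO),
solidity (UKSO), and log₁₀ unsigned-Manhattan-chain-code step counts per axis
(UKUX, UKUY).

**Mixed models and heritability.** Within years,

    y = μ + Z_g g + Z_r r + Z_c c + Z_s s + ε,   g ~ N(0, A σ²_a)

with A the VanRaden additive genomic relationship matrix, row/column blocking
and a 2-D tensor-spline surface as optional spatial random terms (chosen by
AIC over all subsets). Across years a fixed year effect and a genotype-by-year
term are added; GxY is kept only if a boundary-corrected likelihood-ratio test
(½χ²₀ + ½χ²₁) is significant. Variance components come from REML (dense
likelihood, analytic gradients); narrow-sense genomic heritability is

    h² = σ²_a / (σ²_a + σ²_ε)                      (within year)
    h² = σ²_a / (σ²_a + σ²_ge/n + σ²_ε/n)          (across n years)

**QTL scans.** Genotype-class probabilities at markers and pseudomarkers come
from two-flank conditioning under a Haldane Markov chain per parental gamete.
Haley–Knott regression of genotype BLUPs on the expected maternal, paternal
and interaction contrasts gives `LOD = (n/2)·log₁₀(RSS₀/RSS₁)`; genome-wide
thresholds come from 1000 phenotype permutations (80th percentile for the
single-QTL scan, 95th for the penalized-LOD stepwise search). Each hit carries
its 1.5-LOD support interval, marker R² (`1 − 10^(−2·LOD/n)`), and the three
parental contrast effects (AC+AD)−(BC+BD), (AC+BC)−(AD+BD), (AC+BD)−(AD+BC).

**Meta-QTL.** Within a trait group, QTL are nodes of a graph with an edge when
their closed 1.5-LOD intervals overlap on the same linkage group. Every maximal
clique is a meta-QTL: its extents are the max of member left extents and the min
of member right extents (non-empty by the Helly property of intervals), its
position the extent midpoint, reported to 0.1 cM. Stability and group filters
(model count, mean R², population/study/trait counts) are AND-combined.

## Worked example

```bash
cranqtl run --config examples/demo.yaml
cranqtl report --outdir scratch/demo_out
```

The demo simulates a 120-progeny four-way cross on a 3-group map with two
numeric traits — TY with a QTL at 50 cM on linkage group 2 (maternal effect
1.2, paternal 0.8) and UBM with QTL on groups 2 and 3 — plus categorical shape
scores fused into chimera descriptors. The run prints (abridged):

```
blup: {'n_models_fit': 32}
scan: {'n_hits': 10}
metaqtl: {'n_meta': 2, 'n_hits_in': 10}

heritabilities:
 trait     model       h2
    TY      2011 0.442816
    TY all_years 0.850474
   UBM all_years 0.794181
  UKEC all_years 0.059453
  ...

2 meta-QTL:
traits                   models  linkage_group  position  mean_marker_r2
    TY 2011+2012+2013+all_years              2      46.0        0.854949
   UBM      2012+2013+all_years              2      58.0        0.567642
```

Reading this: both simulated QTL regions are recovered as meta-QTL on linkage
group 2, stable in at least three of the four BLUP models (three year models
plus *all years*). The TY peak sits 4 cM from the simulated position — BLUP
shrinkage toward genomic relatives shifts peaks slightly, which is a property
of scanning BLUPs rather than raw phenotypes. Across-year heritabilities
(0.85, 0.79) exceed the within-year ones because year-replicate averaging
shrinks the GxY and residual contributions. The shape descriptors, which were
simulated with no marker linkage, show near-zero heritability and are blocked
from the scan stage by the genotype-significance gate — no false meta-QTL.

Cross-study tables transcribed by hand (same CSV schema; `population` and
`study` columns distinguish sources) drop straight into
`cranqtl metaqtl --qtl qtl.csv --groups examples/groups.yaml`.

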