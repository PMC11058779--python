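# Methods

This note documents the statistical procedures implemented in `riverhealth`,
the default parameter choices and why they were made, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Ecological entities

An ecological entity is the equivalence class of species under exact match
of the guild triple (trophic, habitat, tolerance). With 3 × 4 × 3 = 36
possible triples, a regional species pool maps onto at most 36 entities.
Entities are numbered FE-1, FE-2, … by descending member count, ties broken
by lexicographic (trophic, habitat, tolerance) label order. The numbering is
pure bookkeeping — every set-level quantity (entity count, size multiset,
abundance aggregation) is invariant to it — but fixing it makes catalogs
reproducible across runs and platforms.

Aggregation from species to entity counts is exact integer summation, so
the total number of individuals is conserved; a species present in the
abundance matrix but absent from the guild table is a hard error rather
than a silent drop, precisely to protect that conservation. Relative
abundances and occupancies are reported to one decimal, rounding half away
from zero (the convention of survey tables; banker's rounding differs on
exact .5 values).

## Multimetric indices

Both indices use discrete 5/3/1 scoring: each metric value is compared
against two ordered cut points, taking 5 on the healthy side, 1 on the
degraded side, 3 between. A value exactly equal to a cut takes the better
score — a documented convention; the alternative assignment changes totals
only on exact boundary hits. Totals are sums of metric scores, so the mWPI
(7 metrics) spans [7, 35] and the mIBI-F (8 metrics) spans [8, 40], and
improving any single metric can never lower a total.

Numeric cut points are regional policy rather than theory, so they are
configuration (JSON) with shipped defaults. The default mWPI cuts
(TN 2/4 mg/L, TP 30/100 µg/L, TN:TP 50/100 higher-better, BOD 1/3 mg/L,
TSS 5/10 mg/L, EC 200/450 µS/cm, Chl-a 5/25 µg/L) were chosen so that the
per-cluster score pattern of a temperate wadable-stream survey is
reproduced: reference clusters average in the low 30s, intermediate ones in
the mid 20s, and heavily polluted ones fall to 9–13. The default mWPI class
bands are very poor 7–13, poor 14–19, fair 20–25, good 26–30, excellent
31–35. The mIBI-F cuts and bands follow the same logic at plausible
magnitudes for wadable-stream communities; because published criteria for
the emulated survey are not available, these defaults should be replaced by
program-specific criteria for any real application — all scoring functions
take explicit criteria sets.

Metric subtleties: the riffle-benthic richness metric counts habitat
exactly "RB" (the dual riffle-benthic/water-column guild is a distinct
habitat strategy and is excluded); the native-insectivore metric is the
conjunction of the native flag and trophic "Ins"; the anomaly metric is
inverted (lower is better). Sites with zero individuals have undefined
percentage metrics and are excluded from biological scoring with a logged
sentinel — never given a fabricated score — while remaining in all chemical
stages.

## Chemical clustering

Chemistry is log10-transformed per variable to tame right skew; columns
containing zeros get an offset of half the smallest positive observed value
of that column. Clustering uses the Ward.D2 criterion on Euclidean
distances of the transformed table: the Lance–Williams recurrence on
squared distances with square-root heights, under which two singletons
merge at exactly their Euclidean distance and merge heights are
non-decreasing. All 13 variables enter, including the TN:TP ratio alongside
TN and TP (a flag can drop it; collinearity affects distances only
modestly after the log). No column standardization is applied beyond the
log by default (a z-score flag exists). The number of clusters k is a user
parameter — no automatic selection is attempted — and cluster ids are
renumbered by descending mean mWPI so SC-1 is always the cleanest.

## NMDS

The ordination is Kruskal's nonmetric MDS, written from scratch because it
is the methodological core of the package:

* **Dissimilarity.** Bray–Curtis on entity relative abundances (each site's
  composition sums to 100, removing abundance-scale effects), or on
  mIBI-F metric values range-standardized to [0, 1] per metric — Bray–Curtis
  requires non-negative, commensurate features, and raw metrics mix counts
  with percentages. No Wisconsin or square-root pre-transformation is
  applied by default.
* **Loss.** Stress-1, √(Σ(d−d̂)²/Σd²), with disparities d̂ fitted by
  pool-adjacent-violators isotonic regression of configuration distances on
  the dissimilarity order. Ties are treated weakly (primary approach): tied
  dissimilarities may take disparities in any order, implemented by
  sub-sorting tied blocks by current configuration distance.
* **Optimization.** Steepest descent on stress (disparities held fixed for
  the gradient, refitted after each accepted step) with a backtracking
  step-halving line search, which makes the per-start stress trace
  non-increasing by construction. Defaults: 20 random starts drawn from a
  seeded uniform cube scaled to the dissimilarity range, 300 iterations,
  relative-improvement tolerance 1e-7. The best start wins; non-convergence
  in all starts returns the best configuration with a warning flag.
* **Identifiability.** A configuration is defined only up to rotation,
  reflection, translation, and scale (stress-1 is scale-free). Fitted
  coordinates are centered, rotated to principal axes (axis 1 = maximum
  variance), and sign-fixed so each axis correlates non-negatively with a
  reference covariate (the first feature's site totals by default, or the
  largest-magnitude coordinate made positive). Near-zero-stress solutions
  with coincident points are flagged as degenerate.

Explicit starting configurations can be supplied, which makes the fit
exactly permutation-equivariant: permuting sites and starts together
permutes the site scores identically.

## Gradient statistics

Axis–indicator relations use simple OLS on log10-transformed indicators
(the transform is applied once, inside the routine, and recorded per row).
For one predictor, R² equals the squared Pearson r to machine precision —
asserted in the tests — and slope p-values come from the t distribution
with n−2 df. The correlation screen reports raw p-values with a p < 0.05
mask and pairwise-complete missing handling (per-cell n); a Holm step-down
option exists but is off by default, matching common practice for
exploratory screens. Stream order enters correlations as a numeric variable.

One caveat: NMDS site scores are a function of the full community matrix,
so scores at different sites are not independent draws; the nominal
regression p-values for axis–gradient associations are mildly liberal. The
null-scenario calibration (below) quantifies this: the observed
false-positive rate at α = 0.05 stays near nominal (≈ 5–11% over seeds).

## Synthetic generator

The generator emulates a 41-site, 50-species survey of a temperate river
network on a latent pollution gradient g ∈ [0, 1] (sites evenly spaced):

* **Chemistry.** Pollutant variables are log-linear in g with lognormal
  noise, anchored at clean/degraded values typical of such surveys
  (EC 196→452 µS/cm, TSS 1.8→13.9 mg/L, TOC 1.6→5.8, BOD 0.8→3.2 mg/L,
  TP 11.7→117 µg/L, PO₄-P 0.2→28.3 µg/L, NH₄-N 0.03→0.12 mg/L,
  Chl-a 2.2→77 µg/L). WT, DO, TN, and NO₃-N are near-flat; TN:TP is derived
  as TN/(TP/1000) and therefore declines along g.
* **Guilds.** The default composition plan reproduces the shipped survey
  structure: 19 entities with member counts 8, 6, 5, 4, 3×3, 2×6, 1×6,
  including the ubiquitous generalist (Omn, RB-WC, IS) and sensitive riffle
  insectivores; ~90% of species are flagged native.
* **Abundances.** Negative-binomial counts (dispersion 5 — overdispersion
  is the ecological norm; Poisson is the large-dispersion limit) with
  log-mean linear in g. Response slopes are set at the entity level, member
  species sharing their entity's slope with small lognormal jitter:
  −2.5 for sensitive entities, −1.5 for other riffle-benthic entities,
  +2.5 for tolerant omnivores, +1.5 for other tolerant entities, 0 for the
  generalist, small random slopes otherwise (natural-log units over the
  full gradient). Anomaly counts are binomial per cell with prevalence
  0.005 + 0.06·g, so anomalies ≤ counts by construction.
* **Covariates.** Elevation declines linearly with g plus noise (emulating
  the lowland accumulation of pollution sources, not real topography);
  %forest mirrors elevation, %urban rises with g, %agriculture fills part
  of the remaining share so proportions never exceed 100; stream order is a
  noisy rounding of 2 + 4g clipped to [2, 6].

All draws flow through a single seeded `numpy` Generator, so bundles are
bit-reproducible. A zero-signal variant (all entity slopes 0) provides the
null scenario for specificity calibration.

What the generator does **not** emulate: spatial autocorrelation among
sites, river-network topology, species-level trait variation within an
entity beyond slope jitter, detection/sampling effort differences, and
seasonal dynamics. Passing tests therefore demonstrate that the chain
recovers a planted gradient under idealized sampling — not that any
particular real-world effect size will be reproduced.

## Problem sizes and numerical choices

The test suite and acceptance script run at the emulated survey's scale
(41 sites, 50 species) for full-chain checks; optimizer-vs-oracle
comparisons use small instances where exhaustive enumeration is exact
(length ≤ 8 isotonic fits against all monotone block partitions, n ≤ 8 Ward
trees against a variance-recomputing greedy, 4-point 1-D NMDS against a
dense coarse-to-fine grid search). The null-specificity calibration uses
100 seeded replicates with a lighter NMDS budget (3 starts, 100 iterations)
— under the null any local optimum serves, since the test statistic is the
axis–gradient correlation. Degenerate inputs are handled explicitly:
zero-individual sites (sentinel, excluded biologically), all-zero
dissimilarity rows (error), coincident NMDS points (guarded gradient,
degeneracy flag), zero-variance regression inputs (error, or flat fit for a
constant response), and tied merge heights at a tree cut (resolved by merge
order, logged).

## Known limitations

* Index criteria defaults are illustrative for the emulated region; real
  assessments must supply jurisdictional criteria.
* NMDS finds local optima; with few starts on difficult geometries the
  reported stress can exceed the global minimum (mitigated by the
  multi-start default and the convergence record).
* The correlation screen reports raw p-values by design; with many
  variables, some significant cells are expected by chance.
* Cluster renumbering by mean mWPI presumes the index is informative for
  the region; with uninformative criteria the SC ordering is arbitrary.
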