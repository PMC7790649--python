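# Methods

This note documents the models, rules and numerical choices behind
`dendropatterns`, and what the synthetic generator does and does not
emulate.

## Data model

A *tree series* is one dated annual ring-width sequence (mm/yr) per tree,
obtained by averaging the two measured radii of a stem disk year by year
(`combine_radii`). Years present in only one radius keep that radius's
value, so the merged series spans the union of the two dated spans — this
preserves the full pith-to-bark record used for age. A width of 0 encodes a
locally absent ring and participates in means as 0, consistent with
measured-series semantics. Tucson/rwl decadal files are read and written
with the end-marker convention (999 → 0.01 mm units, −9999 → 0.001 mm);
a long-form CSV (`tree_id,year,width_mm`) is accepted as an equivalent
input for programmatic workflows.

## 20-segment profiles

A series of L ≥ 20 rings is divided into 20 contiguous segments by the
cumulative-quota rule: segment *i* (1-based) covers ring indices
⌊(i−1)·L/20⌋ … ⌊i·L/20⌋−1. This guarantees ring counts differing by at most
one and spreads the longer segments evenly along the series; any rule
meeting the ≤1 bound would be admissible, this one is chosen for
determinism and even spread. Segment means are arithmetic means of the raw
(undetrended) widths: the method deliberately works on raw widths because
absolute growth level is part of the signal separating patterns.

Per-tree growth attributes are age (ring count), mean ring width, sample
standard deviation (n−1), and 5th/95th percentile widths using linear
interpolation between order statistics (the most common percentile
convention; nothing in the method depends on the variant).

For clustering, profiles are stacked into a trees × 20 matrix and each
segment column is centred and scaled to unit sample variance, each segment
acting as one explanatory variable. Scaling parameters are retained so
cluster centers can be mapped back to mm for naming and plotting.

## Pattern identification

k-means is run as `n_restarts` (default 1000) random-initialization
restarts of Lloyd's algorithm, keeping the restart with minimal
within-cluster sum of squares; convergence tolerance 1e-6 on center
movement, at most 300 sweeps. The restart count follows the robustness
practice of running the algorithm many times and keeping the best
partition. The inner loop is scikit-learn's Lloyd implementation; its
empty-cluster relocation rule guarantees the no-empty-cluster
postcondition.

The number of patterns is chosen by maximizing the simple structure index
(SSI), in its size-weighted form: with centers c(k,j) and cluster sizes
n(k), per variable j let span(j) be the max−min center difference, hi(j)
and lo(j) the clusters attaining it (ties resolved as a stable sort), and
d(j) = |mean_k c(k,j) − grand mean|; then

    SSI = Σ_j span(j)·e^(−d(j))·√(n(hi(j))·n(lo(j)))
          / (p · max over attaining clusters of n · e^(−min_j d(j)))

This is the exact formula used by the standard community-ecology
implementation of the criterion, verified against it to machine precision
in the test suite. SSI is invariant to relabelling clusters and to
duplicating every observation. Ties in the argmax break toward smaller k
(parsimony).

Because SSI curves on structure-free data are *not* flat (the index
fluctuates with k on pure noise), a flat-curve test cannot detect a
meaningless selection. Instead the selection is flagged *low confidence*
when the best observed SSI does not exceed 1.4× the best SSI of a
structure-free reference obtained by independently permuting each segment
column of the matrix (preserving marginal distributions, destroying joint
structure). On clustered data the observed maximum is typically ≥2× the
reference; on noise the two are exchangeable.

### Naming rules

Cluster centers are de-standardized to mm and classified by deterministic
rules with configurable thresholds (`LabelThresholds`):

* **linear** — center range < 25 % of its mean width (flat, narrow profile);
* **ascending** — last-third mean is the maximum of the three third-means
  and the first half-mean is below the second (rise without a declining
  tail);
* declining-tail centers (last-third mean ≥ 25 % below the maximum) split
  by the start: **sine** when the first-third mean is below 65 % of the
  center maximum (juvenile suppression before the release hump), **bell**
  otherwise (high growth from the start, i.e. gap-origin trees). The 0.65
  cutoff sits between the ~0.55 start/peak ratio of suppressed-start
  archetypes and the ~0.8 of gap-origin archetypes.

If the three independent shape predicates match exactly one shape the
center is labelled unambiguously; otherwise a deterministic precedence
chain (ascending → sine → bell) decides and the cluster is flagged.
Within a shape group, clusters are ranked by mean center width: one
cluster → level "none"; two → low/high; three or more → low, moderate(s),
high.

## Release detection

%GC(t) = (M₂ − M₁)/M₁ × 100 with M₁ the mean over [t−9, t] and M₂ over
[t+1, t+10] (window anchoring per the cited method's convention: the first
window includes year t). Edge years without two complete windows are
undefined rather than computed on truncated windows, avoiding spurious
early/late releases. M₁ = 0 yields an undefined (flagged) year, not an
exception. Class boundaries are inclusive exactly as printed: ≥ 50 major
release; [25, 50) minor release; (−50, −25] minor suppression; ≤ −50 major
suppression.

Site chronologies report, per calendar year, the percentage of trees with a
defined %GC in each class (denominator = trees with two complete windows
that year), plus combined all-release and all-suppression columns. Curves
are smoothed by loess: local polynomial regression of degree 2 over the
span-nearest neighbours (span = fraction of points, default 0.5) with
tricube weights, fitted by weighted least squares on a centred design. The
implementation is hand-written because the commonly available Python local
regression is degree-1 only; it reproduces polynomials of its degree
exactly and matches a direct weighted-least-squares oracle to 1e-6.

**Peak detection** re-smooths the combined-release percentages at a finer
span (default 0.15) before locating maxima: at the display span of 0.5 on a
~150-year chronology the smoothing window spans ~77 years and merges
episodes 20 years apart, so the four historical release periods would be
unrecoverable from the display curve. Peaks require height ≥ 5 % and
separation ≥ 15 years (about half an outbreak return interval), each
reported with its flanking-minima interval. The 5 % default is calibrated
to the single-release generator (below), where one episode's release
cohort can be as little as ~10 % of the stand; on field data, where trees
release repeatedly and peaks reach 40–75 %, a higher threshold is
reasonable and the parameter is exposed.

The pattern × section frequency table counts a tree for (pattern, section,
class) if *any* year inside that section's calendar span carries the class,
as a percentage of the pattern's trees; the any-year rule is this package's
aggregation choice.

## Stand structure

Dominant height is the mean height of the ⌈100 · area(ha)⌉ tallest living
trees (4 on a 400 m² plot); plots with fewer trees use all of them with a
warning. Canopy layers: dominant ≥ DH; codominant ≥ 2/3·DH; intermediary
> 1/2·DH; suppressed otherwise. A height of exactly 1/2·DH is suppressed —
the intermediary bound is strict. Layer assignment uses all living trees
regardless of crown status; broken crowns matter only when height itself is
compared between groups.

Stand summaries express densities per hectare, basal area per tree as
π·(DBH/2)², species composition as percent of living basal area, and
sapling density from the sapling subplots' own area. Cohorts are assigned
from age cutoffs: cohort 1 contains trees at least as old as the largest
break (established before or at the last primary disturbance); CBAP is
realized as 1 − BA(cohort 1)/BA(all living), which is exact at both
endpoints (0 = single first cohort, 1 = first cohort fully replaced). The
originally cited cohort methodology may weight cohorts differently; only
the endpoint behaviour is fixed by the published description, so the
simple basal-area proportion is used.

## Association tests

The package deliberately replaces two classical procedures with
assumption-light permutation analogues; both substitutions are
methodological stand-ins, not re-implementations:

* *r × c exact test → Monte-Carlo chi-square under fixed margins.* Null
  tables with the observed margins are sampled by Patefield's algorithm
  (scipy's `random_table`) and compared on the chi-square statistic;
  p = (1 + #{perm ≥ obs}) / (1 + B), so the smallest attainable p is
  1/(B+1).
* *Mixed-effects ANOVA with site random effect + Tukey → stratified
  permutation F-test.* Group labels are permuted only within sites, which
  conditions on the site composition exactly as a random intercept is meant
  to absorb site-level differences. Pairwise |mean difference| permutation
  tests are Holm-adjusted and summarized as a compact letter display
  (greedy insertion over groups ordered by descending mean). The optional
  outlier rule (drop below the 1st / above the 99th percentile) is off by
  default. Identical values everywhere make F undefined; this is reported
  as "no difference" (p = 1) rather than an error. Calibration: under a
  null with site strata the test's type-I error is 0.05 ± 0.02 at α = 0.05
  over 500 simulations (checked in the suite).

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular stand. Each tree follows one of nine
archetypes — linear; low/high bell; low/moderate/high ascending;
low/moderate/high sine — built as a deterministic width-level curve times
multiplicative lognormal AR(1) noise (stationary log-sd σ = 0.15, AR(1)
coefficient 0.3 by default; widths strictly positive by construction).

* **Outbreak schedule.** Four episodes by default — 1870–1890, 1910–1940,
  1950–1960, 1975–1990 — with the 1910–1940 episode most severe
  (severities 0.5, 0.75, 0.4, 0.45), matching the region's documented
  outbreak-driven release periods.
* **Release model.** Ascending and sine trees stay at their suppressed
  baseline width until an outbreak releases them, then step to
  baseline × multiplier; sine releases are transient and decline back
  toward baseline. Release years fall in the last three years of an
  episode. The step completes over a short ramp (8–12 % of lifespan):
  besides matching the gradual second-third rise of the observed sine and
  ascending shapes, the ramp removes a discretization artifact — with an
  instantaneous step, where the release year falls *within* one 20-segment
  cell dominates that cell's mean and splits archetypes into spurious
  subclusters. Post-release decline is likewise expressed in relative
  lifetime (total e-folds over the remaining lifespan) so that every tree
  of a template traces the same age-normalized profile regardless of which
  outbreak released it. Hard steps are available via
  `release_ramp_frac = 0`, and a 1.5× hard step reproduces %GC = 50 at the
  boundary exactly.
* **Ages.** The suppressed fraction of life is template-characteristic
  (narrow windows around 0.36 for sine, 0.60 for ascending, 0.75 for the
  recently released moderate-ascending), and an episode is eligible for a
  tree only if the whole window fits inside the 55–271-year age envelope of
  the sampled trees. Bell trees germinate into an outbreak gap (no juvenile
  suppression); linear trees never release and draw ages uniformly.
* **Stand.** Default per-plot counts are 5 trees per template and 1
  high-bell (the rare pattern) on a 400 m² plot — 41 living trees ≈
  1,025/ha, inside the 617–1,700/ha range of the studied stands; eight
  plots by default (328 trees). DBH comes from twice the cumulative ring
  sum with a taper and bark allowance, floored at the 9-cm merchantable
  threshold; height from a saturating Chapman-Richards-type allometry
  (asymptote 17.5 m, rate 0.085/cm, shape 1.5, 6 % lognormal jitter)
  calibrated so dominant height falls in the printed 13–18 m range and all
  four canopy layers are populated. Snags (12 % of living stems) and
  sapling tallies (~4,500/ha) round out the inventory. A truth table
  records template, birth year, release year and cohort per tree for
  recovery scoring.

What the generator does **not** emulate — and hence what passing tests do
not show about field data: cross-dating error, multiple releases per tree
(each synthetic tree releases at most once, which is why synthetic release
peaks are lower than the 40–75 % seen in the field), climate signals and
ring-width autocorrelation beyond AR(1), mortality during the simulation
(snags carry no ring series), spatial structure within plots, and
species-specific growth differences (species labels are drawn independently
of the growth archetype).

## Problem sizes used in the checks

Recovery checks run eight plots (328 trees) at low noise (σ = 0.05) with
500 k-means restarts over k = 2…12 — at this size the SSI argmax identifies
the nine archetypes in ≥ 19 of 20 seeded replicates and labelling is
typically exact. The permutation-test calibration uses 500 null
replications of 60 observations in two site strata with 199 permutations.
The pipeline defaults keep the full 1,000 restarts.

## Known limitations

* The SSI variant is fixed to the size-weighted form of the standard
  implementation; the criterion's originating literature admits variants,
  and nothing here arbitrates between them beyond fidelity to the reference
  implementation.
* "Iterations" of k-means are interpreted as restarts (best-of by
  within-SS), not Lloyd sweeps.
* Shape-naming thresholds are heuristics over cluster centers; centers that
  genuinely straddle two shapes get the precedence-chain label and an
  ambiguity flag rather than an error.
* The permutation analogues answer the same questions as the classical
  tests but are not numerically interchangeable with them (no variance
  components are estimated; p-values are Monte-Carlo).
* CBAP uses the simple basal-area proportion; cohort-weighted variants
  would differ away from the endpoints.
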