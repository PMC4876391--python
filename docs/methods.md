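# Methods

This note documents the statistical methods implemented in `elevbeta`, the
assumptions behind them, the tunable parameters and their defaults, and the
design choices made where the methodology was genuinely open.

## Study design assumed by the pipeline

The pipeline targets replicated elevational transect surveys: each transect
holds a small number of elevational bands (default four) separated by
roughly constant vertical intervals (~200 m), with a handful of replicate
plots per band (default five).  Assemblages are recorded as integer counts
per plot × species.  Where trapping is stratified (e.g. canopy and
understorey traps at the same plot), `pool_strata` sums the strata into one
sample per plot site before analysis; the pooling key is an explicit `site`
column in the metadata, and unstratified rows pass through unchanged.
Because distant transects share almost no species, all similarity,
stratification, decay and indicator analyses are run **within** transects;
mixing transects in one similarity matrix is an error.

## Abundance standardization

Observed richness grows with catch size, so per-plot richness is reported
as Hurlbert's individual-based rarefaction

    E[S_n] = Σ_i [ 1 − C(N − N_i, n) / C(N, n) ],

the exact expected richness of a random draw of `n` of the plot's `N`
individuals.  Binomial coefficients are evaluated as differences of
`gammaln`, which is exact to double precision at any realistic `N`.  The
analytic form equals the mean of the enumerated subsets (tested by
exhaustive enumeration for `N ≤ 12`) and avoids the Monte-Carlo noise of
resampled accumulation curves.  The default depth `n_standard = 364`
corresponds to reading one value per plot off the accumulation curve at the
smallest plot total of a real survey of this design; plots with fewer than
`n_standard` individuals either raise an error or, with `on_small="skip"`,
report NA.

## Common species

Similarity indices computed on presence/absence or proportional abundances
are dominated by sampling noise when most species are singletons.  The
pipeline therefore restricts Sørensen and Bray–Curtis to "common" species,
defined through the detection model

    P = 1 − (1 − 1/n)^N ,

the probability that a species with `N` individuals distributed at random
over `n` equally likely plots appears in at least one sample from a plot.
`common_species_threshold(n, P)` returns the smallest integer `N` meeting
the target: for `n = 5` plots per band and `P = 0.95` the threshold is 14,
and the comparison is inclusive (a species totalling exactly 14 individuals
is common).  Commonness is assessed per transect — the transect is the
habitat within which the no-beta-diversity null of the detection model is
imagined.  Chao–Sørensen and Raup–Crick, which are designed to be robust to
rare species and richness differences respectively, use all species.

## Similarity indices

* **Sørensen** `2a/(2a+b+c)` on common-species presence/absence.
* **Bray–Curtis** `2Σmin(p,q)/Σ(p+q)` on proportional abundances of common
  species.  Proportions are taken relative to the plot's total catch over
  *all* species, so the vectors need not sum to one; this keeps the
  proportions interpretable as shares of the whole assemblage.
* **Chao–Sørensen estimated** `2UV/(U+V)` where `U` (and symmetrically `V`)
  is the estimated total proportion of individuals in one sample belonging
  to shared species: the observed shared proportion plus the correction
  `((m−1)/m)·(f⁺₁/2f⁺₂)·Σ_{shared, singleton in other} x_i/n` driven by
  shared species observed once (`f⁺₁`) or twice (`f⁺₂`) in the other
  sample.  When `f⁺₂ = 0` the divisor uses `max(f⁺₂, 1)` (the standard
  convention), and `U`, `V` are capped at 1.  With no rare shared species
  the correction vanishes and the estimator reduces to the classic
  abundance-based Sørensen — a property the tests assert.
* **Raup–Crick** is computed in closed form: with
  `J ~ Hypergeometric(pool, |a|, |b|)` the shared count of two random plots
  of the observed richnesses drawn equally likely from the transect species
  pool, the index is `P(J < j_obs)`.  The closed form is deterministic and
  matches the verbal definition of drawing random plots from the pool; a
  Monte-Carlo variant with occurrence-frequency-weighted draws
  (`raup_crick_simulated`) is provided for sensitivity analysis, since some
  software weights the null draws by species frequency and the two nulls
  can differ.  A plot's self-comparison is not meaningful for this index;
  the matrix diagonal is NaN and flagged.

## Stratification tests

One-way PERMANOVA on `d = 1 − s`: `SS_total = (1/N)Σ_{i<j} d²`,
`SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²`, pseudo-F from the usual mean-square
ratio.  For a one-way design the Type-III and sequential decompositions
coincide.  The p-value uses unrestricted permutation of plot labels with
the observed labelling counted once: `p = (1 + #{F* ≥ F}) / (1 + n_perm)`,
the standard exact-test convention.  When the number of distinct
plot-to-group assignments is no larger than the requested permutation
count, the test enumerates all assignments instead of sampling — for two
bands of five plots there are only 252 distinct assignments, and random
sampling would merely resample them with noise; permutation software
handles small designs the same way.  Post hoc band-pair comparisons report
`t = √F` on each two-band submatrix with its own permutation p; raw
p-values are primary (the protocol applies no multiplicity correction) and
a Bonferroni column is emitted alongside.  Raup–Crick input is accepted
with a warning (it is non-metric; `SS_among` can then be slightly negative,
and `t` is clamped at 0).

## Distance decay

Elevational sensitivity is summarized by the OLS regression of pairwise
similarity on pairwise |Δelevation| over all within-transect plot pairs,
using realized plot elevations rather than band labels.  Pairs are treated
as independent observations, the convention for descriptive decay fits; an
optional Mantel-style permutation p (permuting plots, refitting) is
available but off by default.  Constant similarity returns slope 0 with R²
reported as 0.  Raup–Crick input is refused unless forced: a probability is
not on a similarity scale where a linear decay rate is meaningful.

## Indicator species and the effect size

For every candidate grouping — each single band and each contiguous band
range, excluding the full gradient (nine groupings for four bands) — the
Dufrêne–Legendre indicator value is

    A = mean abundance inside / (mean abundance inside + outside)   (specificity)
    B = occupied plots inside / plots inside                        (fidelity)
    IndVal = A·B·100 ,

with the multi-band grouping treated as a binary inside/outside partition.
This reduces exactly to the original two-group IndVal and is scale-free per
species.  Each species is assigned the grouping with the largest IndVal;
ties break toward fewer bands, then lower elevation (deterministic).  A
species' maximum IndVal is tested by permuting the plot-to-band assignment
(band sizes preserved), `p = (1 + #{null ≥ obs}) / (1 + n_perm)`,
significant at `alpha = 0.05` by default on raw p-values; a
Benjamini–Hochberg q-value column is emitted for users who want it.

Raw significant-indicator counts cannot be compared across transects whose
species pools differ by an order of magnitude, so the count is standardized
against a null model: each of `n_null` replicate datasets shuffles the
plot-to-band assignment, the **entire** significance procedure is re-run on
the shuffled data, and

    ES = (observed count − mean null count) / sd(null counts) .

`sd = 0` flags the effect size as undefined.  Each null replicate runs its
inner permutation test at `inner_permutations = 199` by default (999 for
the observed data); the effect size is insensitive to the inner count, and
the nested 999 × 999 design is available by configuration.  All permutation
streams are spawned from one seed via independent child sequences, so runs
are reproducible and replicate-order independent.  Note that for a dataset
that genuinely carries no elevational structure the ES is approximately —
not exactly — centred on zero: the significant-count distribution is
right-skewed and bounded below, which leaves a small positive bias in this
predictive t-type ratio (visible as a mean of a few tenths across seeds in
the structureless simulations).

## Synthetic assemblages

`generate_assemblage` emulates the data-generating process the analysis
assumes, with stored ground truth for parameter-recovery tests:

* **Niches**: expected count of species `s` at plot `p` is
  `peak_s · exp(−(elev_p − opt_s)²/(2σ²))`.  Optima are uniform over the
  sampled gradient extended by `niche_center_spread = 200` m at both ends so
  edge bands are not artificially depauperate; `σ = niche_width_sigma`
  (default 200 m) is the single knob controlling elevational sensitivity.
  Gaussian response curves are the simplest model producing gradual,
  approximately linear distance decay; skewed niches are out of scope.
* **Abundances**: peak abundances are log-normal with `meanlog = −1.8`,
  `sdlog = 2.0`.  These values were chosen to match, simultaneously, three
  scales of hyper-diverse light-trapping surveys: ~70–90% of recorded
  species with fewer than 10 individuals, roughly 10–15% of species
  clearing the commonness threshold of 14 (a few hundred common species out
  of 2000), and plot totals of several hundred to ~1500 individuals.
* **Detection**: counts are negative binomial with dispersion `k = 1`
  (variance `λ + λ²`), reflecting the strong overdispersion of light-trap
  catches; Poisson is available for variance-limit tests.
* **Plots**: default 4 bands × 5 plots; plot elevations are jittered
  ±20 m around the band elevation so that decay regressions use realistic
  continuous elevations.
* **Transects**: `generate_multi_transect` concatenates ≥2 transects with
  disjoint species namespaces, mirroring the near-total species turnover
  between distant transects.

What the generator deliberately does **not** emulate: spatial
autocorrelation within bands, canopy/understorey stratification,
phylogenetic or host-plant structure, and observation covariates (moon
phase, weather).  Passing parameter-recovery tests therefore shows the
estimators respond correctly to elevational niche structure under idealized
sampling — not that field data meet these assumptions.

## Problem sizes and numerical choices

* Simulation-based tests use the default 2000-species transects with a
  reduced permutation design (99 nulls × 99 inner × 99 observed
  permutations) and 3–25 seeds per claim; these sizes give stable means for
  the monotonicity and ranking checks while keeping the whole suite fast.
* Permutation comparisons use a tolerance of 1e-9 (IndVal) or 1e-12
  (pseudo-F) when counting `null ≥ observed`, so ties produced by exactly
  equivalent relabelings are counted as exceedances, matching exact-test
  behaviour.
* Rarefaction terms with `N − N_i < n` contribute probability-1 detection;
  all binomials are computed in log space.
* IndVal specificity is defined as 0 for a species absent everywhere; the
  Sørensen/Bray–Curtis of two empty assemblages is defined as 0 with a
  warning.
* `best_indicator` tie-breaking (fewest bands, lowest elevation) makes the
  reported best grouping deterministic; the maximal IndVal itself is
  unaffected.

## Known limitations

* PERMANOVA is one-way only; nested or multi-factor designs are out of
  scope.
* The decay regression inherits the usual caveat that plot pairs are not
  independent; the optional Mantel permutation p addresses inference, but
  slopes remain descriptive.
* NMDS ordination is a visualization hook delegating to scikit-learn's
  non-metric MDS; stress minimization is not part of this package's claims.
* The null model shuffles plots freely within a transect; constrained
  shuffles (e.g. within-band) are not implemented.
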