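# Methods

## The two-step null-model framework

The package partitions pairwise community turnover into five ecological
processes in the standard two-step way.

**Phylogenetic step.**  βMNTD between communities k and m is the mean
distance from each taxon to its nearest relative in the other community,
averaged over both directions; weights are relative abundances by default
(`weighted=False` gives 1/richness).  A taxon present in both communities
is its own nearest relative (distance 0), so βMNTD is 0 for identical
communities.  The null model reassigns taxa to tree tips uniformly at
random — equivalently, applies one random permutation to the rows and
columns of the cophenetic matrix — and recomputes βMNTD.  βNTI is the
z-score of the observed value in that null distribution.  Interpretation
rests on the niche trait being phylogenetically conserved: then low
phylogenetic turnover (βNTI < −2) indicates a shared selective filter and
high turnover (βNTI > 2) divergent filters.

**Taxonomic step.**  Pairs without a significant phylogenetic signal are
split with a Raup–Crick test built on Bray–Curtis.  Each null community
preserves the observed sample's richness — taxa drawn without replacement
with probability proportional to their occurrence frequency across all
samples in the analysis set — and its read total, reads allocated
multinomially proportional to pool-wide summed relative abundances over
the drawn taxa.  RC_bray rescales the percentile of the observed
Bray–Curtis within the null distribution to [−1, 1], counting ties as
half.  Because null totals equal observed totals, Bray–Curtis comparisons
reduce to integer comparisons of shared-read sums, so ties are exact
rather than float-fragile.

**Partition.**  βNTI < −2 → homogeneous selection; βNTI > 2 →
heterogeneous selection; else RC_bray > 0.95 → dispersal limitation;
RC_bray < −0.95 → homogenizing dispersal; else undominated (mainly
drift).  The thresholds are strict inequalities, so boundary values fall
to the stochastic/undominated side.  Pairs whose null standard deviation
is zero (e.g. identical communities) have undefined βNTI, are labelled
`unassigned`, are excluded from process fractions, and are reported
separately.

**Numerical choices.**  n_null defaults to 999 for both nulls (the
framework's convention).  One tip shuffle (and one set of per-sample null
assemblies) is shared by all pairs within a null iteration; per-pair
independent shuffles are available via `shared_null=False`.  Weighted
sampling without replacement uses the Gumbel top-k construction, which is
distributionally identical to successive probability-proportional draws
and vectorizes over iterations.  Randomness flows from one seed through
`numpy.random.SeedSequence` substreams (one per null model), so results
are bit-reproducible.

## Structure–function linkage

Community function is estimated as F(e) = Σ_i f(x_i)·a(x_i), where a(x_i)
is the taxon's relative abundance in the *full* community — not
renormalized over trait-bearing taxa.  The summed relative abundance of
trait-bearing taxa is reported as `coverage`, so the unexplained remainder
is visible rather than hidden by renormalization.  Consistency with
measured function is tested by OLS of measured on estimated (slope,
intercept, R², the slope's coefficient p-value and 95% CI).  Trait-type
classification (I/II/III) takes user-supplied thresholds for "high"
sulfate production and nitrate consumption because the type boundaries are
qualitative; tetrathionate production takes precedence (Type II).

## Descriptive statistics

Shannon diversity uses the natural log.  Jaccard is binary
(presence/absence); Bray–Curtis is computed on counts.  PCoA is classical
scaling of the Gower-centred squared-distance matrix; negative eigenvalues
are reported unchanged and excluded from `proportion_explained` (no
Cailliez/Lingoes correction), and coordinates are returned only for
positive-eigenvalue axes.  PERMANOVA (via scikit-bio) permutes sample
labels freely with the (count+1)/(n_perm+1) p-value estimator.
Rarefaction is an exact multivariate-hypergeometric subsample to the
target depth; samples below depth are dropped with a warning, mirroring
common amplicon practice.  Missing Newick branch lengths are read as 0
with a warning.

## The synthetic-data generator

The generator produces the statistical structure each pipeline stage
assumes, with ground-truth processes for parameter-recovery testing.  Its
defaults mirror the dilution-culturing design the package targets:
12 replicate communities, 5,000 reads per sample, a 64-taxon regional
pool, and optional serial 10-fold dilution of the inoculum ("1 mL into
9 mL", eight levels).

- **Phylogeny**: pure-birth (Yule) trees, ultrametric by construction;
  branch-length jitter optional.
- **Niche**: `niche_dimensions` (default 64) independent Brownian traits.
  A single Brownian trait makes unrelated taxa converge on similar values;
  with many independent dimensions the mean squared niche distance between
  two taxa concentrates around its expectation, which is proportional to
  their phylogenetic distance.  The niche is therefore strongly conserved
  — the premise βNTI interpretation requires — without convergent
  look-alikes.  `evolve_traits` exposes the plain scalar Brownian model.
- **Regional pool**: lognormal species-abundance distribution
  (σ = 1.5 by default; σ = 0 gives a uniform pool).
- **Selection scenarios**: each sample receives a colonizing subset of the
  pool (homogeneous selection; heterogeneous selection uses the full
  pool), then a Gaussian niche filter exp(−s·d²) with a finite niche
  capacity: only the `niche_capacity` best-matching colonists persist
  (competitive exclusion), and reads are drawn multinomially from the
  kernel weights.  Homogeneous selection uses one shared optimum — the
  niche of the taxon whose nearest trait neighbours are closest, i.e. a
  conserved guild; heterogeneous selection spreads per-sample optima by
  greedy farthest-point placement in niche space.  (Mutually separating
  12 optima by several trait SDs is impossible inside a Brownian trait
  range, so maximal spread replaces a fixed separation.)
- **Dispersal limitation**: each sample is colonized by an independent
  random subset (48 of 64), then undergoes Wright–Fisher drift
  (160 generations at population 4,000) — memberships overlap while
  abundances decorrelate, which is exactly what RC_bray detects.
- **Homogenizing dispersal**: samples are mixtures of one common skewed
  core composition (mixing rate 0.97) and small private subsets.
- **Drift**: serial neutral multinomial resampling of the pool
  (5 generations), no weighting.
- **Dilution**: binomial thinning of countable individuals per level;
  `volume_individuals` abstracts cells-per-mL.
- **Function measurements**: the trait-sum estimate plus an optional
  composition-dependent interaction bonus plus Gaussian noise.

Scenario parameters were calibrated so each scenario's βNTI/RC_bray
signature lands in its target region of the partition; the tuned values
live in `SCENARIO_DEFAULTS` (configuration, not logic) and are rescaled
proportionally for non-default pool sizes.  Two pools deviate from the
lognormal default: the homogeneous-selection and dispersal-limitation
scenarios use a uniform pool, because lognormal rarity makes the relevant
colonists (clade members, subset members) fail to arrive and erases the
very signal the scenario defines.  At the reference design (pool 64,
12 samples, depth 5,000, n_null 999) the modal assigned process matches
the generating process for all five scenarios, and selection scenarios
assign ≥ 70% of pairs correctly on seed-ensemble averages — including
held-out seeds not used during calibration.

**What the generator does not emulate**: real 16S phylogenies (clade
structure of an enrichment culture is far more clustered than a Yule
tree), compositional sequencing biases, chimeras or ASV-inference error,
metabolite-mediated interactions beyond an additive bonus term, and the
"equal biomass" transfer normalization of a real serial-transfer
experiment (depth equalization stands in for it).  Passing recovery tests
therefore show the inference machinery is correct and well calibrated on
communities with the assumed statistical structure — not that any real
dataset satisfies those assumptions.

## Degenerate inputs and edge cases

Empty samples are rejected where they would make a statistic undefined
(Shannon, relative abundance, βMNTD, RC_bray).  All-zero sample pairs in
distance matrices yield distance 0 with a warning.  Identical communities
give βMNTD = 0 and undefined βNTI.  Rarefaction of a sample exactly at
depth returns it unchanged.  `align_taxa` keeps the table's taxon order
and logs what it drops; disjoint taxon sets are an error, not a silent
empty result.

## Known limitations

- The βNTI null shuffles all tips of the supplied tree; restricting the
  null to a habitat-specific tip pool is not implemented.
- RC_bray occurrence/abundance weights are computed over the whole
  analysis set, not per group; with very homogeneous analysis sets the
  null loses breadth and RC_bray compresses toward 0.
- Statistical power at a 64-taxon pool is modest: even idealized
  clade-structured communities do not push every pair past |βNTI| = 2, so
  recovery fractions plateau below 1 by construction, not by bug.
- Process fractions are descriptive proportions; no uncertainty intervals
  are attached to them.
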