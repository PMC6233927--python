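# Methods

## The question

When a mitochondrial genome (mitogenome) recovered from a crime-scene or
historical sample matches a person of interest (PoI), the evidential weight
depends on how many other living people carry that same mitogenome.  The
mitogenome is maternally inherited without recombination and mutates slowly
(roughly one mutation per 74–90 generations genome-wide), so sets of
matrilineally related individuals — far beyond recognised relatives — share
a mitogenome exactly.  `mitomatch` estimates, by forward simulation, the
distribution of the number of live individuals matching a random PoI, the
meiosis distance separating matching pairs, and the same distributions
conditioned on a count of the haplotype in a reference database.

## Population model

Discrete non-overlapping generations of `N_g` females; each individual in
generation `g` draws its mother uniformly at random among generation
`g − 1`'s females (Wright–Fisher: offspring numbers are Binomial(N, 1/N),
exchangeable across mothers, no fertility variation).  The final three
generations are the *live* population — the individuals who can appear as
PoIs, matches, or database members — and in those generations an equal
number of males is simulated as additional terminal children (males carry
mtDNA but do not transmit it).  Generation time is implicitly 25 years.

Three canonical scenarios:

| label        | trajectory                                             | live size |
|--------------|--------------------------------------------------------|-----------|
| `300K_const` | 50,000 females/generation, 1,200 generations           | 300,000   |
| `1.2M_const` | 200,000 females/generation, 1,200 generations          | 1,200,000 |
| `1.2M_growth`| 10,257 females for 1,000 generations, then 2%/generation for 150 | ≈1,177,000 |

The growth trajectory's size at growth step k is
`round(10,257 × 1.02^k)`, ending at 200,007 females — "200K" to the
precision that matters; `build_growth_sizes(..., exact_final=200_000)`
rescales the last generation if an exact figure is wanted.

Where the design was open: males are drawn with independent uniform random
mothers (pairing them with female siblings would leave every distance and
count distribution unchanged, since children are exchangeable); individuals
are indexed contiguously per generation, 0-based.

## Mutation model

The mitogenome is binary-coded against the rCRS reference (0 = agrees,
1 = differs) and partitioned into four regions — HVS1+HVS2, PC1+PC2, PC3,
rRNA+tRNA — each with a published 95% HPD interval for the per-site
mutation rate (units: per site per 10^7 generations; shipped in
`data/mutation_rates.tsv`).  Two schemes are available: `rieux`
(16,070 sites) and `oversti` (16,494 sites; a wider control-region
delimitation).

* **Analytic summaries** use interval midpoints.  The genome-wide rates are
  0.01107 (`rieux`) and 0.01372 (`oversti`) mutations per genome per
  generation; over 1,200 generations the expected mutation counts on one
  line of descent are 13.3 and 16.5.  Modelling per-site counts as Poisson
  at the midpoint rate, the probability that some site is hit twice (and
  can revert) over 1,200 generations is 0.0326 / 0.0245.  Note the
  `oversti` genome rate computed from the table midpoints (0.0137) sits
  slightly above the commonly quoted 0.0135, which likely derives from
  posterior means rather than interval midpoints; we report the computed
  value.
* **Simulation** draws one realized rate per region per sequence-evolution
  replicate from Normal(midpoint, (U − L)/3.92) — reading (L, U) as a
  symmetric normal 95% interval — truncated at 0 by resampling (an event
  with probability < 1e-4 per draw for the shipped intervals, logged if it
  occurs).  The realized rate applies to every site of its region and every
  meiosis of the replicate.
* **Mutation dropping**: at each mother–child transmission every site flips
  independently with its region's realized rate.  Implementation: the flip
  count per region is drawn Binomial(n_sites, rate) and flip positions are
  placed uniformly without replacement within the region — exactly the
  per-site Bernoulli law, verified against a literal per-site reference
  implementation by a chi-square test on a 20-site genome.

Haplotype identity is computed on the full genome vector (variant sets are
deduplicated into integer IDs), so lineages that converge by back-mutation
are merged; each individual stores one integer ID and full vectors are
materialized only per distinct haplotype, which is what makes 1.2M-person
populations with ~3M mutation events tractable in memory.

## Founders

Founders receive haplotypes drawn uniformly with replacement from a
database-like pool.  Because no real mitogenome database ships with the
package, a synthetic pool is generated with a specified haplotype frequency
spectrum; the default emulates the diversity of a published US Caucasian
database — 263 entries, 259 distinct (255 singletons, 4 doubletons).  Each
distinct haplotype carries 10–40 variant sites placed uniformly (typical
full-mitogenome distances from the rCRS are a few tens of sites; results
are insensitive to this choice because matching pairs coalesce within a few
hundred meioses, far more recently than the founder generation, so founder
identity only matters through the spectrum's effect on database-diversity
summaries).  Real pools can be supplied via a plain-text format (one
haplotype per line: identifier + comma-separated 1-based variant
positions).

## Matching and the replicate protocol

A PoI is drawn uniformly with replacement from the live population; the
match count x is the number of *other* live individuals with an identical
haplotype ID (an `include_poi` flag switches to the inclusive convention;
the ±1 difference is far below Monte-Carlo noise).  For the first 10% of
PoIs in draw order the meiosis distance — mother–child transmissions
through the most recent common matrilineal ancestor (MRCA) — to every
matching individual is recorded.  Distances are computed by synchronized
mother-pointer climbing, verified exactly against brute-force ancestor
enumeration.

`run_protocol` reproduces the published design: 5 genealogies × 5
sequence-evolution replicates (fresh founder assignment + fresh rate
realization) × 10,000 PoIs = 250,000 PoIs per scenario–scheme combination.
Every stage derives an independent substream from the master seed, so runs
are bit-reproducible and a failed replicate is logged and skipped without
perturbing the others.  Quantiles are type-1 inverse-ECDF (smallest support
value whose cumulative weight reaches q); pooled distributions pool PoIs
across replicates.

**Desk-scale defaults.**  The acceptance script and the end-to-end tests
use one genealogy × one replicate × 10,000 PoIs per scenario (with
distances recorded for 1,000 PoIs in the 300K scenario), which reproduces
the published medians while keeping a full run to a few minutes on one
CPU; tail quantiles (95/99%) are noticeably noisier at this replication
than with 25 pooled populations.

## Conditioning on a database count

A reference database of size n is modelled as a uniform draw without
replacement from the live population excluding the PoI.  Given x, the
database count m is Hypergeometric(N_live − 1, x, n); the conditional
distribution of x given m is estimated by importance-sampling reweighting
of the unconditional PoI draws, with weights equal to that likelihood
(verified against exhaustive database enumeration at N_live = 11 and
against rejection sampling on a 500-individual toy population).  The
effective sample size (Σw)²/Σw² is attached to every conditional
distribution and a warning is raised below 200, since conditioning on
observations far in the tail of the unconditional distribution concentrates
the weight on few samples.  A flag makes the PoI eligible for database
inclusion; the default excludes it.  `n = 0` reproduces the unconditional
distribution exactly.

## Database diversity

`sample_database` draws databases uniformly without replacement and tallies
distinct/singleton/doubleton counts; `diversity_report` summarises
replicate draws boxplot-style (quartiles, 1.5×IQR whiskers, outlier
counts).  Reference constants for the US (263/259/255/4) and Iranian
(352/315/286/24) databases are shipped for comparison lines.  Note the
published boxplot comparisons sample databases of size 351 although the
Iranian database has 352 entries; both sizes are accepted.

## Numerical and degenerate cases

Non-coalescing matrilines get distance `inf` (`UNRELATED`); matching pairs
are essentially always related (a non-coalescing match requires two
mutation-free 1,200-generation lineages, probability ≈ e^(−13) each), and
any such pairs are excluded from distance distributions and logged.
Weighted quantiles use a 1e-12 slack against floating-point accumulation.
Genealogies store one int32 mother pointer per individual (~1 GB for the
1.2M scenario), and the 200K-female genealogy is shared across mutation
schemes within a run.

## Validation against coalescent theory

For a constant population of N females, two random matrilines coalesce at
rate 1/N per generation, so the mean meiosis distance of a random pair is
2N — 100K and 400K for the two constant scenarios.  A 1,200-generation
genealogy cannot exhibit those means directly (at N = 50,000 only ~2.4% of
random pairs coalesce within the simulated depth), so the package exposes
the closed form (`coalescent_mean_pair_meioses`) and validates it by
simulation at N = 500 with deep genealogies, averaging over hundreds of
independent genealogies because the mean pairwise coalescence time of a
single genealogy has an asymptotic coefficient of variation near
√(2/9) ≈ 0.47.

## Known limitations

* **Matching-pair distances run higher than the published table.**  The
  pooled (PoI, match) distance distribution has marginal density
  ∝ exp(−2μt) in the pair's TMRCA t (both lineages must be mutation-free),
  giving a median distance ≈ ln2/μ ≈ 51 meioses for the `oversti` rate —
  which our runs reproduce — while the published medians (23 for that
  scenario) sit near ln2/(2μ), i.e. near the median TMRCA in *generations*.
  Because the match-count tables (which pin the same decay rate through
  clan sizes) agree with our runs, we believe the published distance table
  reflects a different distance convention; we report the meiosis metric
  consistently with the 2N random-pair approximation.
* Heteroplasmy, mixed samples, selection, site-specific rate heterogeneity
  within regions, rate change over time, migration/population structure,
  fertility variation and overlapping generations are all out of scope.
* The synthetic founder generator emulates a database's frequency spectrum,
  not real haplogroup structure; passing diversity comparisons show the
  simulation's spectrum behaviour, not concordance with any real
  population.
* Real databases are not random population samples; the conditioning model
  assumes they are.
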