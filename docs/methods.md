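# Methods

`nimrescue` bundles five computational pieces of a genetic-rescue assessment
for a critically small wild felid population with a captive reserve
population: microsatellite identity/diversity statistics, an allelic-rescue
Monte Carlo, maximum-likelihood spatially explicit capture–recapture (SECR),
a forward-in-time genetic-load simulator, and a pedigree-based population
viability analysis (PVA).  No field data ship with the package; a synthetic
data module generates every input with known truth so each estimator can be
validated by parameter recovery.

## Synthetic data

**Allele specification.**  The canonical microsatellite panel has 8 loci and
27 alleles partitioned by provenance: 17 alleles shared between the wild
(Omani) population and the captive population, 8 found only in captivity (2 of
those only in captive founders wild-sourced from Yemen), and 2 found only in
the wild — so the wild support is 19 alleles and the captive support 25.  The
allocation of alleles to loci is not identifiable from those marginal counts;
the package fixes one allocation satisfying the constraints (2–5 alleles per
locus; the eighth locus monomorphic in the wild) and ships it as a versioned
JSON fixture.  Allele frequencies are drawn per partition from a symmetric
Dirichlet(1.5) over the partition's support, independently between partitions,
so shared alleles differ in frequency across partitions and the partitions
show non-zero F_ST, as real wild and captive populations do.

**Noninvasive genotypes.**  True genotypes are Hardy–Weinberg draws from the
partition of the individual's region; each replicate (scat sample) then
suffers per-allele dropout with probability 0.048 by default — a heterozygote
with one dropped allele is recorded as a false homozygote, both dropped means
a missing locus — plus optional whole-locus missingness.  Dropout is modelled
per allele per replicate because that is how dropout is scored in noninvasive
genotyping.  Sexes are 1:1 by default.  What this generator does *not*
emulate: within-sample PCR replicates (each scat yields one consensus-quality
genotype), false alleles, genotyping error correlated across loci, or spatial
autocorrelation of an individual's samples beyond a shared region label.
Matching performance measured on these data is therefore a property of the
generator's error model, not a calibration of any real laboratory pipeline.

**Spatial capture histories.**  Activity centers are a homogeneous Poisson
process at the configured density over the buffered detector region; each
animal is detected at each detector on each occasion independently with
half-normal probability `g0 * exp(-d^2 / (2 sigma^2))`.  Coordinates are
planar km — over a ~250 km study extent the geodesic error is negligible.

## Identity and diversity statistics

PID(sib) uses the Evett–Weir sibling formula per locus,
`0.25 + 0.5 S2 + 0.5 S2^2 - 0.25 S4`, multiplied across loci.  Diversity
summaries report Na, effective allele number `1/S2`, expected heterozygosity
`He = 1 - S2`, the unbiased form `uHe = He * 2N/(2N-1)`, and allelic richness
rarefied to the smallest per-locus number of gene copies across groups
(El Mousadik–Petit).  The AMOVA operates on squared allele-count distances
between individuals (0.5 times the squared Euclidean distance between allele
copy-number vectors, the GenAlEx codominant metric) with the among-population
Phi-statistic reported as F_ST and p-values from permuting individuals among
groups; the Mantel test and the Smouse–Peakall multilocus correlogram use the
same distance.  The correlogram coefficient is the mean off-diagonal
cross-product of the double-centered covariance matrix within a distance
class over the mean diagonal term; its null expectation is ≈ −1/(n−1), not 0.

**Consensus matching.**  Samples typed at ≥ 5 loci are merged when identical
at all co-typed loci (the strict 100% rule) with consistent sex calls.
Because a single dropout makes a replicate formally distinct from its
siblings, a second pass folds clusters whose consensus differs from another
cluster's only by homozygote-in-heterozygote discordances at ≤ 2 loci (the
dropout signature, directional: the folded cluster is the homozygous one),
requiring the same sex and sampling region and a unique closest target.
Ambiguity blocks a merge.  With the default generator conditions (36
individuals, ~3 replicates each, dropout 0.048) the recovered individual
count falls within ±2 of the truth in ≥ 90% of simulated datasets; the
residual error is intrinsic — chance genotype collisions at 8 modestly
polymorphic loci and unrescuable double-dropout patterns.  A heterozygous
consensus call supported by fewer than two replicates is flagged
low-confidence rather than suppressed.

## Allelic-rescue Monte Carlo

Each replicate draws `n` released individuals without replacement from a
genotyped source pool (or `2n` allele copies per locus from source
frequencies), unions their alleles with the 19-allele wild baseline, and
tallies the count; scenarios report the mean, the empirical 5%–95% band
(type-7 quantiles) and the percent increase over the baseline.  Individuals
mode is the default since releases are of discrete animals.  For pools of
≤ 10 the Monte-Carlo mean is checked against the exact expectation by
inclusion–exclusion over alleles (`1 - C(P-k, n)/C(P, n)` per allele with k
carriers in a pool of P).

## SECR

Binary proximity likelihood for cameras and scat search cells alike (scat
detections are snapped to 1×1 km grid-cell centers).  The full (Poisson-n)
likelihood integrates each individual's detection history over a discretized
habitat mask and multiplies by the Poisson term for the number detected;
optimization is quasi-Newton on transformed scales (log D, logit g0, log
sigma) with three jittered starts, standard errors from the inverse numerical
Hessian, delta-method back-transformed.  Sex is a known individual covariate
on g0 and/or sigma, with the sex proportion a free (logit) parameter when a
sex model is fitted.  Default mask: cells within 4·sigma_init of the
detectors, sigma_init from mean recapture displacement.  Abundance
extrapolation multiplies density by area and reports a lognormal interval —
with the published density 2.30 ± 0.53 per 100 km² over 2213 km² this gives
51 animals with an interval of about 33–79.  Multi-session data are fitted by
summing session log-likelihoods under shared parameters.  Parameter-recovery
tests use a 24-detector grid (6 km spacing), 20 occasions, g0 = 0.1, sigma =
8 km, D = 2.3/100 km², 100 replicates: the mean density estimate recovers the
truth within 10%.

## Forward load simulator

The genome is an exome of 9 autosome pairs × 1000 genes × 1500 bp (13.5 Mb).
Genes are non-recombining blocks (the 1e-9/bp within-gene rate contributes
~1.5e-6 per gene per meiosis, negligible); crossovers occur between adjacent
genes with probability 1e-3 and chromosomes assort freely.  Deleterious
mutations arise at 2.4e-8/bp/generation and neutral ones at 1.6e-8 (3:2).
Fitness is multiplicative, `(1-hs)` per heterozygous and `(1-s)` per
homozygous site, with soft selection: each offspring draws its mother and
father proportional to fitness within sexes (Wright–Fisher,
non-overlapping generations, 1:1 sex ratio).

**DFE and dominance.**  Defaults: gamma(shape 0.2, mean |s| 0.03) for
non-lethals plus a 1% recessive-lethal class (s = 1, h = 0.02), and
`h = 0.5/(1 + 7071 |s|)` — standard mammalian-genetics choices.  Because no
leopard DFE is measurable, `calibrate_dfe` rescales the gamma mean by
bisection on pilot simulations until the equilibrium masked load of a
reference population (N = 200, pilots of 10N generations, common random
numbers across evaluations) hits a target of 6 lethal equivalents; downstream
results are therefore insensitive to the unknown DFE details.  Masked load is
monotone in the scale factor over the relevant range because larger |s| means
lower h under the h–s map, hence more heterozygous (hidden) load.

**Load accounting.**  Per individual, on the linear lethal-equivalents scale:
realized = Σ_hom s + Σ_het h·s, total = Σ_hom s + Σ_het s, masked = total −
realized.  Linear is the default because homozygous lethals stay finite; an
exact −ln(fitness) decomposition (`scale="log"`, realized ≡ −ln w) is
available and satisfies masked + realized = total as an identity.  Mutations
fixed in every tracked population are pruned from genotypes and accumulated
separately as drift load, since they shift absolute but not relative fitness.

**Neutral burn-in.**  The very long neutral phase needed to equilibrate
neutral diversity is replaced by a coalescent initialization: msprime
generates equilibrium neutral variation (with recombination matched to the
gene-block rate) which is loaded onto the founding haplotypes; neutral
mutations continue to arise forward in time.  π is computed from neutral
allele frequencies as `Σ 2p(1-p) · n/(n-1) / L`.

**Scenario scale.**  The published scenario (ancestral N declining 1000→110,
captive N = 64 for 24 generations, releases of 0–8 per generation for 20
generations) is supported directly, but tests and examples run a reduced
scale chosen to preserve the qualitative contrasts while remaining fast:
ancestral N = 120 (burn-in 1000 generations), wild decline 120→40 over 16
generations, captive N = 12 for 16 generations, releases k ∈ {0, 2, 8} for 12
generations, metrics averaged over generations 7–12, 16 paired replicates
(each k runs from the same burn-in snapshot).  At this scale the simulator
reproduces the qualitative rescue results: total load declines with sustained
releases (the small captive line purges lethals), while realized load is
minimized and fitness and π are maximized at the small release cohort — large
cohorts swamp the wild population with the captive line's reduced diversity
and its own homozygous load.  A `rescaled(factor)` helper scales mutation and
recombination rates for runs that scale N and time down by the same factor.

## PVA

Individual-based yearly cycle: breeding (monogamous annual pairing by
default; female first breeding at 3 years, two-year inter-birth interval,
litters of 1–3 with probabilities 0.5/0.4/0.1, maximum age 15), mortality by
age class, truncation to the carrying capacity K = 500 by uniform culling,
and every fifth year an optional supplementation event adding captive-born
adults (1:1 sex ratio, unrelated to residents, carrying their own allele
labels).  Inbreeding depression acts on first-year survival as
`S = S0 · exp(-F · LE)` with F the pedigree inbreeding coefficient (recursive
kinship) and LE the lethal-equivalents parameter (default 6.29; the doubled
sensitivity value is used verbatim as 13.58 even though 2 × 6.29 = 12.58).
Juvenile (age 0–2) mortality defaults to 20%; adult mortality defaults to
14%, chosen so the unsupplemented baseline is near-stationary — consistent
with a population judged roughly stable over two decades — which is the
regime where the lethal-equivalents assumption visibly separates scenarios:
at LE = 6.29 supplemented populations stay at or above their starting size,
while at LE = 13.58 unsupplemented populations decline steeply.  Successive
supplementation cohorts are modelled as unrelated founders; relatedness
accumulating within a real captive source would weaken the rescue effect,
so the supplemented trajectories are optimistic in that respect.  The
sensitivity grid varies mortality (10–25%), LE (6.29, 13.58) and cohort size
(0, 2, 6, 10) because the life-history defaults are judgement calls.

## Numerical choices and limitations

- Haplotypes are id-sorted integer arrays stored columnar (one flat array +
  offsets per population); gamete formation, fitness and load accounting are
  single compiled (numba) kernels.  Recombination switch points are drawn
  inside the kernel from a seeded generator, so runs are reproducible for a
  fixed seed and library version.
- SECR mask integration is a midpoint rule over cell centers; halving the
  default cell size changes log-likelihood by well under 0.1 at the default
  buffer.  Non-convergence or a singular Hessian is flagged on the fit
  object, never silently NaN.
- AMOVA variance components are truncated at zero; permutation p-values use
  the add-one rule.
- The ±2-individual accuracy of consensus matching is specific to the
  generator's error model (see above); real datasets with PCR replication
  within samples should do better.
- Monte-Carlo orderings (the k = 2 optimum) are tested at reduced scale with
  paired replicates and rank tests; single runs at these sizes are noisy and
  should not be over-interpreted.
- The PVA does not model catastrophes, density-dependent reproduction or
  genetic management; the load simulator has no beneficial mutations, no
  overlapping generations and no sex chromosomes.
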