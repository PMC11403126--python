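# Methods

This note documents the models behind `kinbreed`, their assumptions, the
parameters that matter, and the numerical and design choices made where
the design was genuinely open.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic mating system

The simulator is the package's ground truth.  It emulates a polygamous,
dioecious freshwater-crayfish-like system with one or two reproductive
bouts ("cohorts") per year.

**Breeding model** (`simulate_breeding`).  Per cohort, each breeding
female mates with `m ~ ZTPoisson(mean_mates_per_female)` males — the
zero-truncated Poisson was chosen because field estimates report only a
range (1–7 mates) and means around 2.8 ± 1.7, not a distribution; the
truncation encodes that a berried female has mated at least once.
Paternity shares within her clutch are Dirichlet with concentration
`male_skew_concentration` (default 0.5, which typically gives one sire
the majority of the clutch, matching the dominant-sire pattern reported
for this mating system).  Every mate receives at least one offspring when
the clutch size allows, so the realized sires per clutch equal the drawn
mate number except in tiny clutches.  Clutch sizes are negative binomial
(mean 8, size 2 by default; no literature value exists for northern
invasive populations, so these are explicitly uncalibrated placeholders).
Breeder sex ratio is set by `n_males` / `n_females` (default 1:1 — the
motivating study is silent on this).

**Cohort carryover.**  A fraction `parent_carryover_prob` of one cohort's
breeders (dams, and realized sires) breeds again in the next cohort; the
remainder of each cohort's pool is drawn from never-bred adults.  Two
consequences used by tests: carryover 0 gives disjoint parental pools
across cohorts, and carryover 1 re-uses every breeder.  Carried breeders
are *forced* to reproduce (carried sires are distributed round-robin as
extra mates if the random draw missed them); without that, "a breeder
carries over" would be a statement about pool membership rather than
realized parentage, and the carryover probability would not be
interpretable against the cross-cohort shared-parent detector.

**Genotypes** (`simulate_genotypes`).  Founders are drawn in
Hardy–Weinberg proportions at ALT frequencies uniform on `maf_range`
(default (0.05, 0.5]); offspring receive one allele per parent
independently per locus (gene dropping).  Loci are organized into RAD
tags (`snps_per_tag`) spread round-robin over `n_chromosomes` (default
94, the chromosome count of the motivating organism), which gives the LD
estimator its between-chromosome pair structure and the one-SNP-per-tag
rule something to select against.

**Observation model** (`apply_observation_model`).  Each of a genotype's
two allele copies flips with probability `error_rate` (default 0.01, the
error prior used for sibship reconstruction in the field workflow).  The
implied genotype discordance — `2e(1-e)` for heterozygotes,
`1-(1-e)^2` for homozygotes — is the binomial oracle the tests check.
Read depth is negative binomial with mean `mean_depth` (28, the observed
mean effective depth in the motivating dataset) and size
`depth_dispersion`.  The default size is 15 (per-call SD ≈ 9): the
published "SD = 23.3×" describes variation among per-*sample* mean
depths, and a per-call dispersion that extreme would make the 20-read
genotype mask plus the 75% call-rate screen destroy essentially every
locus — incompatible with the fact that a ~930-SNP panel survived that
exact cascade.  Calls at depth 0, plus a `missing_rate` Bernoulli
dropout, are missing.  Allelic depths are binomial given the observed
genotype (ref-read probability `1-e`, `0.5`, `e` by genotype).  Site
QUAL is synthesized so a `qual_fail_rate` fraction fails the QUAL < 20
screen.

**Growth** (`simulate_growth`).  Carapace length = `growth_intercept_mm`
(5 mm at hatch) + `growth_rate_mm_per_day` × age + N(0, `growth_sd_mm`),
floored at 1 mm.  The default 0.05 mm/day keeps spring-captured
fall-cohort juveniles below the 20 mm adult threshold, reproducing the
small-in-fall / larger-in-spring full-sib pattern that motivates
sibship-based cohort merging.  Capture dates prefer the sampling dates
within ~9 months of birth (juvenile-targeted trapping); individuals born
after the last date are unsampled.

**What the generator does not emulate** — and hence what a green test
does not establish: population structure and migration between
waterbodies, inbreeding, linked-locus transmission (loci are dropped
independently; between-tag LD arises only from pedigree structure), sex-
or size-biased trapping, age-dependent fecundity, and sperm storage
across cohorts.  Conclusions about robustness to those features require
the real data path.

## 2. Filtering

`filter_cascade` applies, in order: site QUAL < 20; minor allele count
< 3; site missingness > 0.99; per-genotype mask below 3 reads; individual
missingness > 0.99; per-genotype mask below 7 reads; locus call rate
< 0.75; observed heterozygosity > 0.6; allele balance outside
[0.4, 0.6] (computed as Σ AD_ref / Σ AD over heterozygous calls; sites
with no het reads are exempt and logged); optional one-SNP-per-RAD-tag
selection (lowest missingness, then highest MAF, then first position);
then the regime screens — juvenile: individuals > 50% missing, 20-read
genotype mask, MAF ≥ 0.005; paternity: individuals > 75% missing,
20-read mask, MAF ≥ 0.3.  Site statistics are recomputed at the step
where each is applied, on the calls surviving at that point; "greater
than" thresholds are strict.

Two deliberate choices:

* The "minimum of 20 reads" regime rule is a *per-genotype* mask by
  default (parallel to the 7-read rule); a per-site mean-depth variant is
  available via `FilterConfig(depth20_per_genotype=False)` because the
  published wording ("kept loci with a minimum of 20 reads") is ambiguous
  between the two.
* After the regime steps a **fixpoint re-screen** re-applies the site and
  individual screens on the final call set until stable.  Depth masking
  changes call rates and allele counts computed at earlier steps; without
  the re-screen the cascade is not idempotent and its output can violate
  its own thresholds.  The re-screen is reported as one extra step.

## 3. Kinship and sibship reconstruction

**KING-robust φ** uses heterozygote sharing and opposing-homozygote
counts over pairwise-complete loci; it requires no allele-frequency
estimate and is robust to structure.  φ(self) = 0.5 exactly; expectation
0.25 for parent–offspring and full sibs, 0.125 for half sibs, 0 for
unrelated.

**Pair classification** compares four IBD classes — U (1,0,0),
HS (½,½,0), FS (¼,½,¼), PO (0,1,0) — by per-locus joint genotype
likelihoods under sample allele frequencies, with observed genotypes
related to true ones by the symmetric per-allele error ε (default 0.01).
The error model removes zero-probability cells, so log-likelihoods are
finite for ε > 0.  Numerical choices: probabilities floored at 1e-300
before log; allele frequencies clipped to [1e-6, 1-1e-6]; pairs sharing
fewer than 100 called loci are `uncallable`; argmax ties break toward
the less-related class (U > HS > FS > PO) to be conservative; PO calls
within a same-generation juvenile set are coerced to FS with a logged
warning (a juvenile cohort cannot contain its own parents).  Allele
frequencies are estimated from the full sample, mirroring the
"unknown allele frequencies" setting of the full-likelihood tool this
module stands in for; founders are assumed non-inbred (the original tool
allowed inbreeding — not emulated here).

**Families** are connected components of the FS-classified graph after a
transitivity repair: while some A–B and B–C are FS edges but A–C is
classified otherwise, the involved FS edge with the smallest likelihood
margin is dropped.  Half-sib links are aggregated *between* families by
majority vote over cross-family pair classes, weighted by the mean
margin of the HS calls.  `Q_FS` and `Q_HS` are the full- and half-sib
pair frequencies implied by the final partition.

**Parent reconstruction** (`infer_parents`).  Each family owns two latent
parent slots; each shared parent corresponds to a *clique* of families
in the half-sib graph.  Half-sib edges are therefore grouped by triangle
closure (two edges sharing a family belong to the same parent when the
third side of the triangle is also a half-sib edge); connected
components of that edge graph become shared slots, and any family placed
in more than two groups keeps the two largest/heaviest.  An earlier
design — greedy slot merging edge-by-edge in weight order — proved badly
order-fragile under polygamy (parent counts off by 40–70% on two-cohort
scenarios); the clique view recovers true parent counts exactly on true
partitions and is the package's own design choice.  Full-likelihood MCMC
sibship reconstruction is intentionally *not* reimplemented; the
Colony2 exporter keeps that door open.

**Known-mother paternity** (`count_sires`).  For each offspring pair in
a clutch, the likelihood that they share the sire (full sibs) is
compared with different sires (maternal half sibs), conditioning on the
mother's observed genotype and marginalizing the unknown sire(s) over
Hardy–Weinberg at sample frequencies; the same transitivity repair turns
pairwise decisions into clusters, and the cluster count is the inferred
sire number.  Offspring with opposing-homozygote conflicts against the
mother at > 5% of shared loci (at ε = 0.01) are flagged "maternity
suspect" and left out of clustering — the analogue of a clutch member
assigned to a different inferred female in the field data.

## 4. Breeder-number estimators

**Sibship frequency.**  `N̂b = 4 / [(1+3α)(2 Q_FS + Q_HS)]` with α = 0
(random mating / no inbreeding; α is exposed as a flag because the
original analysis allowed inbreeding but reports no α).  CIs are
percentile bootstrap over offspring (families resampled through their
members), 500 replicates by default; whether the published CIs came from
the likelihood or resampling is unstated, so the bootstrap is labelled
as such.  `Q_FS = Q_HS = 0` yields +∞ with the finite lower bound kept.

**Linkage disequilibrium.**  Mean squared Pearson correlation of dosages
(the Burrows-composite-comparable choice under random mating) over all
between-chromosome locus pairs with pairwise-complete individuals;
supplying a chromosome map excludes physically linked comparisons
without discarding loci.  The sampling expectation `1/S + 3.19/S²`
(S ≥ 30; `0.0018 + 0.907/S + 4.44/S²` below) is subtracted at the
harmonic-mean S, and N̂b follows the random-mating quadratic.  `r²' ≤ 0`
or a negative discriminant give +∞.  The CI is a leave-one-locus-out
jackknife: normal-theory on the mean r², transformed through the
monotone N̂b formula (bounds swap).  No MAF screen is applied inside the
estimator — panels are caller-supplied.  Note the estimator assumes
drift–recombination equilibrium; validation simulations therefore breed
the ideal population for several generations before sampling (a single
generation from LD-free founders carries only ~3/4 of the equilibrium
LD and biases N̂b upward by ~40%).

**Chao asymptote.**  Offspring are incidence samples, parent slots are
species: bias-corrected Chao2
`N̂s = Ns + ((m-1)/m)·a1(a1-1)/(2(a2+1))` with the classical
incidence-based variance (the `a2 = 0` branch uses the homogeneous-case
variance).  The widely used R implementation (`vegan::specpool`) applies
a slightly different variance formula; the point estimate is identical.
The accumulation curve is the mean distinct-parent count over random
offspring orderings (100 by default).

**Rarefied reproductive success.**  `n_sub` offspring (default 75, the
comparable-cohort size used in the motivating analysis) drawn without
replacement, RS = mean offspring-per-parent among parents appearing in
the subsample (= 2·n_sub / distinct parents); mean, SD and percentile
95% CI over 1000 replicates.  Parents without offspring are unobservable
in this design, so RS ≥ 1 by construction.

**Coancestry.**  `Θ = (0.25 n_FS + 0.125 n_HS) / C(n,2)` from the
partition's pair counts — the non-inbred-parent kinship values for full
and half sibs.

## 5. Cohorts, shared parents, contrasts

Cohort assignment bins juveniles (carapace < 20 mm — the field
convention; larger "juveniles" are excluded with reason `oversize`) into
breeding-season windows: captures from `season_start_month` (default
August) through July of the next year form one bin, because reproduction
in the motivating system is concentrated in late summer/fall and
spring-caught juveniles are the previous fall's hatch.  Bins are merged
whenever a full-sib pair spans them; the original study fixed cohorts by
inspection, and this merge rule is the module's formalization of its
stated evidence (size–frequency, date, sibship).  Cohorts under 10
individuals are dropped (`tiny cohort`), mirroring the removal of a
five-individual cohort in the field data.  Assignment is invariant to
input row order.

`shared_parents` requires one *joint* sibship analysis over all groups:
parent slots from separate inference runs are not comparable, and the
API enforces this by taking a single `InferredPedigree` plus an
offspring→group map.  Cross-group sibling pairs are classified FS (two
shared slots) or HS (one).

`treatment_contrast` reports percent change in the Chao asymptote and in
rarefied RS between two result sets, with CI-overlap flags (Chao overlap
uses ±1.96·(SE_a + SE_b); RS uses the percentile CIs).

## 6. Permutation test

The statistic is the ratio of within-group median KING φ.  The null
permutes *individual* group labels, preserving group sizes — never the
pairwise values, which are dependent through shared individuals and
whose permutation would be anti-conservative.  Two-tailedness folds the
statistic as |log T|; p carries the add-one correction, so the smallest
attainable p is 1/(n_perm+1).  Because φ medians of weakly related
groups sit near zero, the ratio scale degenerates there: if any observed
or permuted median is ≤ 0 the whole test falls back to the difference of
medians (logged).  Whether the original analysis permuted individuals or
pairs is unstated; individual-level permutation was chosen for validity.
Screening group pairs for low differentiation (the F_ST < 0.1 rule)
is the caller's responsibility.

## 7. Determinism and scaling

Every stochastic routine takes a seed or Generator; the pipeline fans a
single seed into per-stage seeds via `SeedSequence.spawn`, and equal
seeds give byte-identical manifests.  Pair classification is vectorized
and chunked (2048 pairs × loci at a time); the all-pairs stage is
O(n² L) and handles ~500 juveniles × ~1000 loci in well under a minute
on one core.  Validation simulations in the test suite run at the sizes
their criteria state (e.g. 50 pedigree replicates, 30 LD replicates,
200 calibration datasets); nothing is gated behind markers or
environment variables.

## Known limitations

* Half-sib detection from pairwise likelihoods is intrinsically noisier
  than full-sib detection; `Q_HS` and therefore the sibship N̂b inherit
  that noise at small panels (< ~300 SNPs).
* The pairwise classifier assumes non-inbred, unstructured samples;
  within-waterbody structure inflates apparent relatedness.
* Triangle-closure parent grouping can fuse two true parents connected
  through coincidental half-sib triangles when family sizes are 1–2.
* The LD estimator's equilibrium assumption makes it upward-biased for
  cohorts founded by a single colonization pulse.
* Colony-format export is structural: it has not been validated against
  a live Colony2 run inside this repository.
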