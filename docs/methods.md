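# Methods

## Data model

The substrate of every statistic is a sites × samples matrix of haploid
allele indexes (0 = reference, 1.. = alternates, −1 = missing), ordered
strictly by 1-based reference position over a default genome length of
134,525 bp (the Nipponbare chloroplast).  Chloroplasts are maternally
inherited and effectively haploid, so diploid-coded VCF genotypes are
collapsed: homozygous calls become the single allele, heterozygous calls
are treated as artifacts and become missing (a "major allele" policy is
available for pipelines that prefer to keep them).  Coordinates are
1-based inclusive at every external interface (VCF/GFF convention);
internal interval work is half-open 0-based where it matters.

MAF uses non-missing calls only and, at multiallelic sites, is the
frequency of the second most common allele.  The high-quality filter
removes a site when missingness is strictly greater than 0.20 **or** MAF
is strictly below 0.01, so sites sitting exactly on either threshold
survive; the filter is idempotent and retained + removed always equals
the input count.  Ts/Tv is counted over biallelic SNPs only.

## Diversity and differentiation

Per-site diversity is the unbiased gene diversity
h_i = n_i/(n_i−1) (1 − Σ_a p_a²) with n_i the non-missing calls at the
site, which equals the mean pairwise difference among the callable
sequences.  Windowed π sums h_i over a window and divides by the window
*length* (invariant positions included), giving the conventional
per-site scale; windows are anchored at position 1, default 1000 bp with
500-bp steps, and the terminal partial window is reported with its true
length.  Sites with fewer than two callable sequences are skipped.

F<sub>ST</sub> follows Weir & Cockerham (1984) reduced to haploid data:
with two groups the hierarchy collapses to a one-level ANOVA on allele
indicators.  Per site and allele, MSP = Σ n_i(p_i−p̄)²/(r−1),
MSG = Σ n_i p_i(1−p_i)/Σ(n_i−1), n_c = (Σn_i − Σn_i²/Σn_i)/(r−1), and
a = (MSP−MSG)/n_c, b = MSG, summed over alleles.  The *weighted*
multi-locus estimate is Σa / Σ(a+b) across sites, not a mean of
per-site ratios.  Sites monomorphic across both groups, or with fewer
than two calls in either group, are skipped.  The estimator is
deliberately not clamped at zero: for identical equal-size groups it
equals −1/(n_c−1) exactly, the familiar finite-sample bias at zero
differentiation (the test suite asserts this algebraic value).

Tajima's D uses the full 1989 constants computed from the subset size n,
with S counting sites polymorphic among the subset's non-missing calls
and π_total the summed unbiased site diversity.  S = 0 yields NaN with a
warning.  The default is one whole-genome value per group; a windowed
mode reuses the 1000/500 grid.

PCA operates on the mean-centered allele-count matrix with missing
values imputed to the site mean (scikit-learn backend).  MDS is
classical metric scaling (principal coordinates, scikit-bio backend) of
normalized Hamming distances computed over pairwise-complete sites.

## Selection scan

The diversity-reduction ratio π_w/π_c is taken per window between a
reference group (wild rice by default) and a focal cultivated group on
an identical window grid.  Windows whose denominator diversity is below
1e-9 are undefined and excluded from ranking — mapping them to +inf
would let monomorphic windows dominate the tail.  The cutoff is the
(100 − 2.5)th percentile (linear interpolation) of defined ratios;
windows at or above it are selected, so ties at the cutoff are all
included (conservative), and overlapping/adjacent selections merge into
candidate regions.  Because the ratio direction is genuinely ambiguous
in common usage, both the reference and focal groups are arguments, and
the scan is run separately per cultivated group.

## Haplotype network

Samples sharing an allele vector over the retained sites form a
haplotype; samples with any missing call at a retained site are excluded
by default (pairwise-complete matching can create non-transitive
identity and is off by default).  InDel sites count as single mutational
steps; a SNP-only switch exists.

The connection limit is the statistical-parsimony criterion: the largest
number of observed differences j that can, with 95% confidence, be
attributed to j distinct single mutations (no superimposed changes).
The probability is computed as a posterior under a neutral-pair model:
the mutation count M separating two sequences is geometric (its mean
moment-matched to j), mutations fall uniformly and independently over
the m sites, and P(D=j | M=k) — k uniform mutations occupying exactly j
distinct sites — follows the stable occupancy recurrence
L(k,j) = L(k−1,j)·j/m + L(k−1,j−1)·(m−j+1)/m.  The limit is monotone
non-decreasing in sequence length, and a confidence near zero connects
any modest distance (capped at `max_steps`).  For the full chloroplast
length (134,525 bp) the 95% limit evaluates to 117 steps.

The network is built agglomeratively: haplotype pairs in increasing
Hamming-distance order (ties broken by larger haplotype frequency, then
lower index — deterministic output), joining only pairs in different
components; a join at distance d threads d−1 inferred intermediate
nodes so every edge is one mutational step; pairs beyond the limit
never join.

## Introgression scan

Derived-allele frequency is the non-reference frequency among
non-missing calls (no outgroup polarization; multiallelic alternates
pool).  A site is group-B-specific iff its derived frequency is strictly
greater than 0.95 in B and strictly below 0.05 in A, and vice versa.
Presence of the derived allele in wild rice is annotated as a flag
rather than filtered, with an opt-in strict exclusion switch.  Each
accession is profiled by the fraction of opposite-group diagnostic
alleles it carries; the candidate-introgressant threshold (0.10) is a
declared default, not an empirical claim.

## Bottleneck tests

For each locus passing the MAF ≥ 0.05 pre-filter (strict "<" removal),
the equilibrium distribution of unbiased gene diversity conditioned on
the observed allele count k and gene count n is simulated: Kingman
genealogies, Poisson(θ/2 × branch length) mutations, allele states per
model (IAM: each mutation a novel allele; SMM: ±1 on an integer ladder;
TPM: single-step with probability 0.70, else a geometric jump with
variance 30 — both exposed as configuration), θ tuned so the expected
allele count matches k (Ewens' formula for IAM, a short stochastic
search otherwise), and replicates accepted only when exactly k alleles
appear (error below 1% acceptance).  Loci sharing (k, n) share one
simulation.  DH = (He_obs − Heq_mean)/Heq_sd per locus; significance is
a one-tailed Wilcoxon signed-rank on DH for excess plus a binomial sign
test whose reference excess proportion is estimated from the same
simulations rather than fixed at ½.

Two caveats are intrinsic.  First, SMM/TPM assume a stepwise allele
ladder that SNP alleles do not possess; they are provided to complete
the classical three-model design, but IAM is the model whose
assumptions match chloroplast SNPs.  Second, the summary tests assume
independent loci, while every site of a non-recombining chloroplast
shares one genealogy; with fully linked loci the dataset-level p-value
is noisier than nominal.  The calibration studies therefore use the
generator's unlinked-loci mode (below).

## Synthetic data

The coalescent generator draws a Kingman genealogy (pairwise
coalescence at rate j(j−1)/2), drops Poisson(θ/2 per unit branch
length) infinite-sites mutations, and assigns each mutation a unique
uniform coordinate, so E[S] = θ·a1 and E[π_total] = θ; the calibration
tests check both within 5% at 500 replicates and mean Tajima's D within
±0.15 of 0.  An `n_loci` option splits θ across independent genealogies
to emulate unlinked loci.  The structured generator adds, per group,
independent coalescent variation, planted fixed differences between a
designated pair, planted private sites at explicit frequencies, uniform
missingness, and single-base-insertion InDel emission; everything
planted is recorded in a truth dictionary/JSON.  All generators are
pure functions of (config, seed).

The bottleneck-signature generator prunes each polymorphic site with
probability 1 − (2·maf)^severity: severity → 0 keeps everything (the
neutral limit), severity 0.8 removes most singletons while keeping
intermediate-frequency sites, reproducing the excess-diversity-per-
allele-count signature of a contraction without simulating the
demography itself.

What the generator does *not* emulate: sequencing error, alignment
artifacts around the inverted repeats, non-uniform mutation rate along
the genome, back-mutation (infinite sites), or real InDel length
spectra.  Passing tests therefore demonstrate correctness of the
statistics and recovery of planted signals under clean haploid data,
not robustness to those real-data pathologies.

## Problem sizes and numerical choices

The default test and acceptance runs use desk-scale conditions chosen
to keep Monte-Carlo error well below the asserted tolerances: diversity
oracles on ≤ 12 × 50 random matrices; FST checks at 20 samples/group
with ~200 sites; coalescent calibration at n = 10, θ = 5, 500
replicates; bottleneck calibration on 20 datasets of n = 20, θ = 20
over 40 unlinked loci with 300 accepted replicates per (k, n);
the acceptance script's study-like panel uses 68 accessions across four
subgroups.  Percentiles use linear interpolation; NaN propagates for
undefined quantities (D at S = 0, ω at Ks = 0, JC at p ≥ ¾) rather
than being silently zeroed; multi-hit NG86 pathways through stop codons
are excluded, and if every pathway is blocked the differences count as
nonsynonymous.
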