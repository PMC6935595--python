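# Methods

`treesel` implements a multiscale screen for selection in a nonmodel tree
sampled as a multi-population diploid panel: sequence-diversity and
neutrality statistics per gene and region, SNP-climate association scans, a
gene-level binomial outlier test combined with external association calls,
and polygenic (SUMSTAT) pathway enrichment with pruning and empirical FDR.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Data model

Genotypes are unphased diploids. Every statistic operates on *allele
copies*: an individual contributes two copies per site, and no formula used
here requires phase. The dataset-level genotype matrix stores copy counts
(0/1/2) of the **globally defined minor allele** — the less frequent allele
over the full sample, with frequency-0.5 ties broken toward the
lexicographically smaller allele string so that results are reproducible
across runs and platforms. VCF positions are kept 1-based as read; any
internal interval arithmetic is 0-based half-open.

## SNP filtering

The quality cascade keeps biallelic, polymorphic SNPs with missing fraction
strictly below 0.15, mean coverage in the closed interval [20, 250], and
heterozygote allele balance in [0.3, 0.7]. A SNP failing several rules is
attributed to the first failing rule in that order, so per-rule counts always
sum to the number removed. Bounds are closed because "between a and b" is
read as inclusive.

The paralog screen removes SNPs with a significant *heterozygote excess* in
at least 4 populations. Per SNP and population we use the one-sided exact
Hardy-Weinberg test: conditional on the minor-allele count among the 2n
copies, heterozygote counts of matching parity are enumerated and the upper
tail P(N_het >= observed) is computed. The per-population level is alpha =
0.05. The exact test is chosen because population samples are small (10
diploids); populations with fewer than two genotyped individuals are "not
testable" and never count as significant.

## Diversity and neutrality statistics

Per site j with n_j >= 2 observed copies and allele counts {c_a},

    h_j = n_j/(n_j - 1) * (1 - sum_a (c_a/n_j)^2),

the unbiased per-site heterozygosity (equal to the mean pairwise difference
at the site). Class diversity is sum_j h_j w_j / sum_j w_j with fractional
Nei-Gojobori site weights (w_syn = fraction of the three single-base changes
of the codon position that are synonymous; changes to stop codons count as
nonsynonymous), the denominator running over *all* accessible sites of the
class, monomorphic included. Sites with fewer than two observed copies are
excluded from numerator and denominator. Multi-allelic sites are retained
(the formulas generalize); eta counts alleles-minus-one per site and eta_s
counts alleles observed exactly once at polymorphic sites.

Tajima's D uses the classical constants. Fu & Li's starred (outgroup-free)
D* and F* use the corrected coefficient expressions adopted by mainstream
implementations; the original publication's printed coefficients contain
known typos, and two corrected variants of the F* variance term circulate.
We adopted the variant whose normalization calibrates under the neutral
coalescent — mean near 0 and variance near 1 across (n, theta) — verified by
simulation during development; the alternative variant produces a negative
variance estimate and is degenerate. The classical formulas assume a fixed
sample size; with missing data the statistics use the modal per-site
observed copy count by default (`n_mode="max"` is available), and this
choice is flagged in the output.

The t-approximation, modal-n, and per-site-n_j conventions mean that on real
resequencing data our numbers can differ in the third decimal from tools
that handle missingness by complete-case deletion; the behavior of any
particular external tool is not replicated bit-for-bit.

Inbreeding F is the method-of-moments estimator (O_hom - E_hom)/(M - E_hom)
with E_hom = sum_j (1 - 2 p_j (1 - p_j) n_j/(n_j - 1)); relatedness is the
unadjusted A_jk of the GCTA lineage, reported raw (no clipping), with the
1 + F variant on the diagonal. Both plug in sample allele frequencies, so
very small panels carry the usual -1/(n-1) bias; the clone screen (duplicated
individuals show A_jk > 0.6) is unaffected.

Regional summaries report per-site diversity over a caller-supplied surveyed
length when one is given (a SNP panel lacks its monomorphic sites; guessing
a length would silently misreport pi). pi_syn and pi_nonsyn always keep
class-specific accessible denominators so pa/ps remains a ratio of per-site
class diversities.

## SNP-climate association

Per SNP and population, the minor-allele frequency over observed copies;
populations with no data at a SNP are dropped pairwise. Spearman's rho is
the Pearson correlation of mid-ranks; the two-sided p comes from the t
approximation t = rho sqrt((m-2)/(1-rho^2)), with |rho| = 1 mapped to p = 0.
At m = 12 populations with ties from discrete frequencies, the approximation
is slightly liberal: its realized size at alpha = 0.01 is about 0.012 in our
null simulations. An exact permutation p would remove this but is
unnecessary here because the downstream gene-level test estimates its
expected rate from the realized scan output, which absorbs the calibration
error. Pairs with fewer than 4 usable populations or zero frequency variance
are emitted as untested.

## Gene-level binomial outlier test

For each (variable, period) column: per gene, n tested SNPs and a
significant ones; the pooled expected rate P = sum(a_i) / sum(n_i) over
genes with a_i > 0 (excluding zero-outlier genes makes P conservative,
following the top-candidate convention; the mean-of-ratios alternative is
available as `pool_rule="mean-ratio"`). A gene is flagged when a strictly
exceeds the smallest integer q with BinomialCDF(q; n, P) >= 0.9999. SNPs in
a gene are correlated through linkage, so the binomial model understates the
null variance; the 0.9999 quantile and strict inequality keep the test
conservative in practice (measured null flag rate well below 1e-3).
Columns are tested separately per (variable, period) by default; a
periods-merged mode is a matter of re-keying the input.

The combination rule retains a flagged gene when at least 2 distinct SNPs of
that gene are significant for the same variable — and same period by default
(`match_period=False` relaxes this) — in at least one of the two consumed
external methods (Q-value < 0.05 or Bayes factor > 30), pooled per SNP with
OR semantics. External methods are consumed as a call table, never rerun.

## Pathway enrichment (SUMSTAT)

The SUMSTAT of a set is the sum of a per-gene statistic over members. The
null is the SUMSTAT of random same-size gene subsets drawn uniformly
without replacement from the universe of genes with a defined statistic
(default 100,000 draws); a normal is fitted by moments and p-values are
normal tails, so they can resolve below 1/n_draws (an empirical-quantile
cross-check is available via `SumstatNull.draw_sums`). Both tails are always
computed; the tested side is configured and recorded.

Pruning removes redundancy between overlapping sets: emit the set with the
smallest tail p (ties: larger |z|, then lexicographic id), delete its genes
from all remaining sets, drop sets that fall below the minimum size
(default 5), repeat until none remain. The sampling universe stays fixed
through pruning.

Pruned p-values are biased low, so FDR is estimated empirically: permute the
gene-to-statistic assignment (preserving set sizes and overlap structure),
rerun the full prune-and-test pipeline (default 300 iterations), and set
Q(p) = E_null[#{p' <= p}] / #{observed <= p}, monotonized to be
non-decreasing in p. Candidate calls use Q < 0.15. Because label permutation
does not change the multiset of universe values, the subset-sum null
distribution is identical in every iteration; one set of cached null moments
per subset size therefore serves the observed run and all iterations — an
exact economy, not an approximation — and makes 300 iterations cheap.
Results are bit-identical given (seed, n_draws, n_iter).

Numerical note: the normal approximation to the subset-sum null is excellent
for near-normal universes, but a small finite universe realizes skewness of
its own. Exactness checks against exhaustive enumeration therefore use a
universe of exact normal scores (distribution quantiles), the idealized
symmetric case; against a random 12-value draw the approximation error can
reach ~0.05 in the shoulders, driven by the draw's own skewness rather than
by the method.

## Climate tools

Seasonal aggregation averages December-February (calendar-year convention:
December of the same record year), March-May, June-August and
September-November. Calibrated climatic distance is the unweighted Gower
form: the mean over variables of |source - garden| / observed range, with
ranges computed over sources plus the garden unless supplied; it is
symmetric, bounded by 1 when deviations stay inside the ranges, and
invariant to affine rescaling of any variable. Trait-climate associations
are Pearson correlations of population means with an exclusion list for
poorly replicated populations. The common-garden mixed models themselves are
out of scope.

## Synthetic data

`simulate_coalescent_gene` is a single-population Kingman coalescent with
infinite-sites mutation (exponential coalescence at rate C(k,2), Poisson
mutations at theta/2 per lineage per coalescent time unit), the calibration
fixture for the sequence statistics; Watterson's E[S] = theta * a_n is its
closed-form oracle.

`simulate_population_panel` emulates the study design: 12 populations of 10
diploids, ~1,100 genes averaging ~23 SNPs each, 8 climate variables over 3
periods with cross-period correlation 0.7 on each variable's natural scale.
Neutral SNPs draw population frequencies from a Balding-Nichols beta around
a global frequency (single differentiation parameter, default 0.1 —
moderate-to-strong structure as in a fragmented, low-gene-flow tree).
Planted clines are gene-concentrated: a clinal gene gets one (variable,
period), and half its SNPs follow frequency = logistic(a + beta*z + noise)
with beta = 2 on the logit scale and noise sd 0.3 (roughly the
between-population scatter the differentiation parameter implies). Gene-wise
planting is needed for the gene-level test to see the multi-SNP signals it
is designed for; scattering single clinal SNPs across genes yields
gene-level recall near zero at any realistic density. The external-call
simulator marks planted SNPs significant with sensitivity 0.8 per method and
null SNPs at a 0.01 false-call rate.

What the generator does **not** emulate: linkage disequilibrium within
genes (SNPs are conditionally independent given population frequencies),
isolation-by-distance or admixture structure beyond the single-parameter
model, spatially autocorrelated climate, collapsed paralogs (the
heterozygote-excess screen is exercised only by constructed fixtures), and
coalescent-scaled diversity in the panel (panel SNP frequencies are not tied
to a mutation rate). Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the assumed sampling model,
not robustness to the full complexity of real resequencing data.

`simulate_pathway_universe` draws standard-normal gene statistics, shifts
one designated set by delta, and optionally nests one set inside another to
exercise pruning.

## Problem sizes in the test suite

The suite runs at desk scale: 200 random alignments for the diversity
oracle; 1,000 coalescent replicates (n = 20, theta = 5) for neutrality
calibration; 5,000 genes for the outlier-test null; all 495 size-4 subsets
of a 12-gene universe plus 2,000 sets for SUMSTAT exactness and uniformity;
50 seeded replicates (10,000 draws, 100 FDR iterations, 20 sets) for
planted-pathway detection. Detection of a 1-SD, 10-gene shift in a 300-gene
universe is intrinsically marginal: across fresh seeds the rate is roughly
0.75 +- 0.04 and depends on how many competing null sets the collection
contains; the fixed-seed suite documents 42/50.

## Known limitations

- Replicating a published regional diversity table requires the original
  deposit including invariant sites; per-site scaling here always demands an
  explicit surveyed length.
- No LD-aware correction in the binomial outlier test beyond its
  conservative quantile; no structure-corrected association (external
  structure-aware methods enter through the call table).
- No sliding windows, haplotype statistics, or outgroup-polarized
  (unstarred) Fu & Li tests.
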