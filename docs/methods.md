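# Methods

`lactovar` implements a quantitative-genetics pipeline for dissecting the
genetic architecture of milk production traits with mammary multi-omics
functional classes: defining the classes (tissue-specific genes, miRNA
regulators, RNA-editing sites), partitioning genetic variance across them
with multi-GRM REML, testing class enrichment against a circular-permutation
null, and using the classes as priors in genomic prediction.  Every stage is
exercised end-to-end on synthetic cohorts with known ground truth.

## Phenotypes and the variance-component model

Phenotypes are deregressed predicted transmitting abilities (dPTA): a bull's
PTA divided by its squared reliability, which strips parental contributions
so records behave as quasi-independent observations.  The base model is

    y = 1 mu + sum_f g_f + e,    g_f ~ N(0, G_f sigma2_f),   e ~ N(0, I sigma2_e)

with one genomic relationship matrix (GRM) per variant set.  GRMs follow
VanRaden's first method, `G = Z Z' / (2 sum p_j (1 - p_j))`, with dosages
centred by twice the observed alternate-allele frequency; monomorphic
variants drop out of both numerator and denominator, so `G` is invariant to
panel duplication and variant order.  Heritability is `h2 = sigma2_g /
sigma2_P`; the per-class proportion is `h2_f = sigma2_f / sigma2_P`; and the
per-variant enrichment of class f is the odds ratio

    enrichment = (h2_f / h2_all) / (n_f / n),

where `h2_all` sums the fitted class proportions and `n_f / n` is the
class's share of variants.

dPTAs are treated as homoskedastic by default.  Reliabilities are carried
through the tables, and `fit_reml(reliability_weights=...)` offers a
1/reliability residual weighting, but it is off by default since nothing in
the deregressed records' construction here requires it.

### REML estimation

`fit_reml` maximizes the restricted likelihood by average-information (AI)
updates with an EM warm-up step and an EM re-step whenever an AI step would
leave the feasible region; components are bounded below by a floor of
1e-8 x var(y).  AI/EM iterations crawl when a component approaches the zero
boundary (pure-noise data) or when two GRMs are nearly collinear (random
variant splits of an unlinked panel), so if the likelihood has not settled
within 50 AI iterations the fit switches to a bounded quasi-Newton (L-BFGS-B)
maximization of the exact restricted likelihood using the analytic score as
gradient, and convergence is then declared by a KKT check: interior
components need a vanishing score, boundary components a non-positive one.
Standard errors of the variance components come from the inverse AI matrix
at the optimum, and standard errors of the proportions by the delta method
on that matrix.

Multi-class fits assign variants overlapping several classes to the first
class in a caller-supplied priority order (default: the order the classes
are given in), because simultaneous GRMs require disjoint variant sets.  The
per-chromosome partition fits one GRM per chromosome jointly and reports the
OLS regression of per-chromosome proportion on chromosome length (slope,
adjusted R2, p), the classic check that polygenic variance scales with
chromosome size.

### Circular-permutation null

To ask whether the variants around a set of genomic sites (e.g. RNA-editing
sites with a ±100 kb window) capture more variance than position alone
predicts, the autosomes are concatenated into a circle of length L, the
whole site set is advanced by one random offset R ~ U[1, L] and wrapped
modulo L, the flanking windows are re-expanded around the shifted sites, and
the two-GRM partition is refit.  A single global shift preserves every
circular inter-site distance, hence the clustering structure of the class;
re-expanding windows after the shift (rather than shifting intervals) keeps
the construction identical between observed and null classes.  The empirical
p-value uses add-one smoothing, p = (1 + #{null >= observed}) / (n_perm + 1),
so it is never exactly zero; each permutation index draws from its own
spawned RNG stream, making the null reproducible and order-independent.
Null classes that happen to contain no variants are redrawn.  Calibration
requires the observed sites to be exchangeable with their shifts: sites
placed *at* variant positions produce systematically larger observed classes
than shifted ones and anti-conservative p-values, which is visible in the
test suite's calibration check.

## Functional-class definition statistics

**Tissue specificity.**  Expression is log2(x + pseudo) transformed
(pseudo = 1e-3, configurable) and each gene standardized to mean 0, SD 1.
Specificity of a gene for a target tissue is the OLS t-statistic of a
+1/−1 tissue-indicator column in a regression that also carries an intercept
and optional covariates (project, breed, sex as one-hot factors with
singleton levels merged; age numeric).  Samples from tissue categories
related to the target (e.g. other mammary tissues when testing lactating
mammary) are excluded before fitting, so the contrast is target vs clearly
unrelated tissues.  Specific genes are the top 10% by t, ties at the cutoff
included.  A design note: standardizing each gene *within each tissue*
(one reading of "Z-score normalization within each tissue") zeroes every
per-tissue mean and with it the very between-tissue contrast the t-statistic
measures; the default is therefore global per-gene standardization, with the
within-tissue variant available as `preprocess(center="tissue")` for
dispersion diagnostics only.  Genes with zero variance get t = 0 and are
ineligible for the top fraction; zero residual variance yields an infinite-t
sentinel.

**miRNA prioritization.**  For each miRNA, Pearson correlations against all
mRNAs are computed with two-sided p from the t approximation (n − 2 df).  An
mRNA is "negatively correlated" when r < 0 and p <= 0.05 (inclusive, as the
threshold is conventionally quoted).  A 2x2 table over the expressed-mRNA
universe — negative vs not, predicted target vs not — is tested with a
one-sided Fisher exact test for enrichment of negatives among targets
(two-sided available by flag).  A miRNA is a candidate when its Fisher
p < 0.05 **and** the variance proportion captured by its target-region class
exceeds 0.1, both strict inequalities.  The candidate/DE overlap test is a
Yates-corrected chi-square, falling back to Fisher when an expected cell is
below 1.

**RNA editing.**  Detection follows the hyper-editing strategy: reads that a
strict initial alignment rejects (here: more than 3 mismatches) are A→G
collapsed along with the reference and re-placed; a read consisting mostly
of A→G editing then matches cleanly.  Realignment is an exact-seed plus
Hamming-extension matcher (ties leftmost, unplaced reads discarded) — the
published pipeline delegates this step to a general-purpose aligner, but the
fixtures here are ungapped so a purpose-built matcher preserves the method's
logic at desk scale.  Placed candidates are screened on the original
sequences: A→G count >= 5% of read length (>= 3 for reads <= 60 bp), A→G
fraction of all mismatches > 0.8, mean Phred > 25, N fraction <= 10%, no
mono/di-nucleotide motif repeated more than 10 times, no homopolymer run
over 20 bp (the repeat rules are operational interpretations; both are
configurable).  The library is unstranded, so T→C sites are folded onto the
A→G channel, merging counts at shared loci.  Editing level combines the
mapped pileup with recovered reads:

    level = (mapped G + unmapped G) / (mapped depth + unmapped G),

zero when the denominator is empty.  Sites within 100 bp chain into clusters
(single linkage, boundary inclusive).  Stage comparison calls a site
stage-qualified when present in every sample of a stage; specific = exactly
one stage, common = both; common sites are tested for level differences with
a Wilcoxon rank-sum test under Benjamini–Hochberg control at 0.05 (the test
choice is ours; the source analysis names only an adjusted p threshold).

## Genomic prediction

GBLUP and MultiBLUP solve the mixed-model equations on the reference
animals; validation animals receive genomic values purely through the
reference–validation GRM block, never their phenotypes.  GBLUP with a
VanRaden GRM is algebraically identical to SNP-BLUP (ridge regression on
centred dosages with lambda = sigma2_e / sigma2_beta), which the test suite
verifies to 1e-6 relative error — the two routes share no code.

BayesR places SNP effects in a four-component normal mixture
N(0, gamma_k * sigma2_beta), gamma = (0, 0.01, 0.1, 1), with mixing
proportions pi drawn from a Dirichlet(1,1,1,1).  The single-site Gibbs
sampler (numba-compiled) samples per-SNP components from the marginal
likelihoods, effects from their normal conditionals, the two scales from
scaled-inverse-chi-square conditionals (nu = 4, scales set from var(y)), and
pi from its Dirichlet conditional; no thinning, posterior means over all
post-burn-in draws.  The gamma values multiply one common scale sampled in
the chain — the variant of BayesR that fixes component variances as
fractions of the genetic variance differs by a constant and is not
implemented.  BayesRC is the same chain with separate Dirichlet-updated
mixing proportions for variants inside and outside the functional
annotation; an empty class falls back to BayesR with a warning.  Prediction
accuracy ("reliability") is the squared Pearson correlation between genomic
values and validation dPTAs, x100, displayed at two decimals; increases are
computed before rounding.  Deregression is implemented literally as
PTA / reliability^2.

Panel construction utilities mirror routine practice: QC (sample call rate
>= 0.90, variant call rate >= 0.90, MAF >= 0.05, 1-df chi-square HWE
p >= 1e-6, in that order, boundaries inclusive), LD pruning (greedy
keep-first within a 1 Mb sliding window at r2 > 0.9; the window and
keep-first rule are this package's choices — deterministic and order-stable),
and panel merging keyed by (chrom, pos, alleles) with the base copy kept.

## Synthetic data

The generators define the study conditions for every test:

- **Genotypes**: unlinked biallelic dosages Binomial(2, p), p ~ U(0.05, 0.5)
  by default; positions uniform over chromosomes.  No LD, no relatedness —
  so GRM off-diagonals concentrate near zero and REML standard errors are
  close to the unlinked-theory optimum; recovery results here do not speak
  to LD-induced biases in real panels.
- **Effects/phenotypes**: per-variant mixture component drawn from its
  class's pi over gamma = (0, 0.01, 0.1, 1); genetic values and noise
  empirically rescaled so realized h2 equals the target (the source study is
  empirical and states no generative scale; exact rescaling makes recovery
  tests sharp).  The dPTA stand-in is g + noise whose per-animal variance
  scales as 1/reliability, reliabilities U(0.8, 0.99).
- **Expression**: N(0,1) log2 baseline, planted specific genes shifted by
  +effect_size in their tissue, emitted on the raw 2^x scale with tissue,
  category, project, breed, sex, age metadata.
- **miRNA system**: true regulators get a stated fraction (default 0.8) of
  their listed targets generated at correlation ~ −corr_strength, with
  regulated mRNAs disjoint across regulators so truth is unambiguous.
- **Edited reads**: reads tile a random reference at a stated depth; planted
  sites sit at A positions in clusters (default 8 sites within 80 bp —
  editing is clustered in real transcriptomes and the hyper-editing screen
  requires >= 3 edits per read, so isolated low-level sites are invisible to
  it by design); per-read site state Bernoulli(level); uniform per-base
  error; reads with <= 3 mismatches are flagged as initially mapped.

Seed determinism is bit-exact everywhere (`numpy.random.default_rng` with
spawned streams for parallel structures).

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen so each check
has adequate statistical power: heritability recovery uses 20 cohorts of
n = 2000 x m = 5000 (the mean estimate is then accurate to ~±0.01);
permutation calibration uses 200 cohorts of n = 150 with 19 shifts each and
a randomized-PIT KS test (the add-one estimator is discrete, and subtracting
a seeded U(0, 1/(n_perm+1)) jitter makes its null distribution exactly
uniform); prediction comparisons use n = 500 x m = 2000 with 5,000 MCMC
iterations (1,000 burn-in) per chain and 10 replicates.  The full-scale
analysis the package mirrors ran 25,000 iterations with 5,000 burn-in; the
defaults keep those values.

Other numerics: mean imputation of missing dosages per variant (after QC,
before GRM/LD); GRM positive-semidefiniteness tolerated to −1e-8 x trace/n;
Fisher p-values from the exact hypergeometric tail (validated against full
enumeration for all tables with n <= 30); singular BLUP systems receive a
1e-8 ridge with a warning; LD-prune threshold comparisons treat r2 = 1
duplicates as prunable even at r2_max = 1.

## Limitations

- No LD or pedigree structure in simulated genotypes; class-partitioning
  behaviour under strong LD leakage between classes is untested.
- The editing realigner is ungapped; spliced or indel-bearing reads are out
  of scope.
- The per-class mixture model ignores annotation uncertainty: classes are
  treated as known, disjoint (after priority resolution), and fixed.
- Reliability weighting of dPTAs, dominance/epistatic components, bivariate
  REML, and single-step methods are not implemented.
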