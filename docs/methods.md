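# Methods

`rankqtl` implements an eQTL-mapping pipeline for a structured livestock
population — concretely, a two-breed F2 cross of 145 cows in five
full/half-sib families — in four stages: pedigree-based decorrelation of
expression, an adaptive linear rank test per SNP-transcript pair,
genome-wide Benjamini-Hochberg FDR control, and cis/trans classification.
A generative simulator with the same statistical structure provides the
validation substrate, since the pipeline's target data (array expression
plus ~37k SNP genotypes) cannot be bundled.

## Pedigree relationships

The numerator relationship matrix A is built with the tabular method over
a validated, topologically ordered pedigree: `A_ii = 1 + A_fm/2`,
`A_ij = (A_jf + A_jm)/2`, with unknown parents treated as unrelated,
non-inbred founders (no founder relationships are assumed; the dam side of
the founder generation is taken as unrelated). Ids are strings compared
exactly. A dense representation is used throughout — the pedigrees here
are a few hundred animals, so Henderson's sparse-inverse machinery would
be over-engineering. Correctness is anchored against a Monte-Carlo
gene-dropping estimator (unique founder alleles dropped through the
pedigree; A entries estimated as twice the mean allele-pair IBD
indicator), agreeing within 3 Monte-Carlo standard errors at 10^5
replicates.

## The sire-dam mixed model

Per transcript the model is

    y_i = s_j + beta * x_i + 1/2 (a_if + a_im) + e_i

with fixed year-season class `s_j` (25 levels by default) and age at
slaughter `x_i` (days), and random parental additive effects `a` with
covariance `sigma2_a * A_par` over the parent generations (each phenotyped
animal loads 0.5 on its sire's and 0.5 on its dam's effect). The residual
absorbs the Mendelian-sampling deviation; the REML residuals
`y - X bhat - Z uhat` are the decorrelated expression passed downstream.

REML is computed by profiling the variance ratio `lambda =
sigma2_a/sigma2_e`. The kernel `K = Z A_par Z'` is transcript-invariant,
so one symmetric eigendecomposition per dataset diagonalizes the model for
every transcript; the restricted likelihood then reduces to a 1-D
bounded Brent search in `lambda` over [0, 1e3] (absolute tolerance 1e-8).
`lambda = 0` is admitted (OLS limit) and flagged; constant transcripts are
emitted with zero residuals and a degenerate flag; per-transcript failures
are flagged rows, never batch aborts. Season levels with zero observations
are dropped (treatment coding, first observed level as reference); a
rank-deficient design raises an error naming the collinear columns. Tests
cross-check residuals and variance components against an independent
dense-matrix REML (slogdet likelihood, 2-D Nelder-Mead over log
variances): residual correlation > 0.999 on simulated transcripts.

## Adaptive linear rank test

Stage 1 computes two Hogg-type selector statistics on the pooled sample,
label-blind. With `L_p`, `M_p`, `U_p` the means of the `ceil(pN)`
smallest/middle/largest order statistics,

    Q1 = (U.05 - M.5) / (M.5 - L.05)    (skewness; 1 for symmetric data)
    Q2 = (U.05 - L.05) / (U.5 - L.5)    (tail weight)

The middle block is taken symmetrically with fractional edge weights when
`N - ceil(pN)` is odd, which makes Q1 exactly 1 on exactly symmetric
samples and gives the reflection identity Q1 -> 1/Q1, Q2 -> Q2 under
x -> -x. The selector needs n >= 8 and non-degenerate spread; otherwise
the procedure falls back to Kruskal-Wallis and says so.

Stage 2 maps (Q1, Q2) to a score family through a precedence-ordered,
YAML-configurable decision table. The default partition (a standard
Hogg-style choice; the exact cutoffs are not fixed by theory and are
deliberately a configuration artifact):

| rule (first match wins) | test        |
|-------------------------|-------------|
| Q2 <= 2                 | short tails |
| Q2 >= 7                 | median      |
| Q2 >= 4.5               | long tails  |
| Q1 >= 2                 | right skew  |
| Q1 <= 0.5               | left skew   |
| otherwise               | Kruskal-Wallis |

Score families (c = (N+1)/2): Wilcoxon `a(R) = R`; median `1{R > c}`
(half at R = c); long tails = winsorized Wilcoxon `clamp(R - c, +-N/4)`;
short tails `R - c` on the outer quartiles and 0 on the middle half;
right skew `min(R, ceil(c))`; left skew `max(R, floor(c))`. Ties get
mid-rank score averaging, and the statistic's variance uses the realized
scores, which is the automatic tie correction. The k-sample statistic

    T = (1/s^2) sum_g (A_g - n_g abar)^2 / n_g

is referred to chi-squared with k-1 df; with Wilcoxon scores and no ties
it equals the classical Kruskal-Wallis H exactly. Because the selector
ignores group labels, conditioning on it leaves the permutation null
untouched, so the two-stage test is level-alpha; Monte-Carlo checks at
n = 145 confirm the level within 3 binomial SE at alpha = 0.05 and 0.01
for normal, lognormal, t3 and uniform data.

A permutation mode (full enumeration for N <= 10, otherwise seeded
Monte-Carlo) exists for validation. At N <= 10 the chi-squared p tracks
the exact mid-p within 0.05 for Wilcoxon scores; coarser score families
(median scores take three distinct values at n = 9) have null atoms wider
than that, so no continuous approximation can do better — the permutation
mode is the recommended path at such sample sizes. This is irrelevant at
the pipeline's operating point (n ~ 145 per test).

The selector is computed per SNP-transcript pair on the analyzed
subsample (after dropping missing genotypes), configurable to once per
transcript (`selector_scope`).

## Scan, FDR and classification

Every SNP x transcript pair is tested on the shared samples; samples
missing the genotype are dropped pair-wise; genotype classes with fewer
than `min_group_count = 3` members are dropped and the pair is skipped
(and counted) if fewer than two classes remain. The BH step-up adjustment
uses m = the number of tests actually performed — skipped pairs are not
part of m — and accepts an external m larger than the p-vector so chunked
scans adjust correctly. Significance is `p_bh <= alpha` (inclusive),
alpha = 0.1 by default. Companion Kruskal-Wallis and one-way ANOVA
p-values are carried per record.

Classification is by chromosome: cis = SNP and gene on the same
chromosome, trans = different chromosomes, unknown = SNP without a mapped
position. Distance is `|snp_pos - gene_start|` (strand-ignored, 1-based),
defined only for same-chromosome pairs. Window-based re-classification
(1 Mb and 5 Mb by default, strict `<`) is reported alongside: within
window = cis, any other known-position record = trans, unknown positions
tallied separately rather than folded into trans. Two closed-form
utilities express the published threshold arithmetic: `equivalent_fdr =
alpha * m_sub / m_total` (the BH per-test threshold re-expressed on a test
subset) and `threshold_from_rejections = k * alpha / m`.

## QC

Samples with more than 10% missing genotypes are excluded first; then
SNPs with more than 10% missingness or minor allele frequency below 5%
(boundaries strict per the stated wording, MAF computed on non-missing
calls of surviving samples — computed after sample exclusion, and the
report records this). Pedigree consistency uses per-trio Mendelian
incompatibility (opposing homozygotes and impossible trio configurations
via a gamete-set table; missing calls skip the site) rather than full
likelihood-based genotype elimination — equivalent at trio depth for
biallelic markers and far simpler. Chip-version merging is reduced to an
intersect-on-snp-id utility. PLINK text input counts the minor allele at
read time (a .ped file carries no ref/alt); all tests downstream are
invariant to 0<->2 coding flips.

## Simulator

The generator's defaults are the study conditions: 5 purebred sires, five
F2 families of 49/35/52/8/1 cows (145 total), 25 year-season classes
assigned cyclically, ages uniform on 1300-1500 days. The pedigree is
MOET-style: family i runs through one F1 bull (son of sire i) mated to
F1 dams sired by sire i+1, about four F2 per F1 dam, a P0 dam pool of 33
recycled across F1s — giving ~38 P0 parents; the published totals fix the
family sizes and founder counts but not the internal mating design, which
is a package choice.

Genotypes: founder haplotypes drawn per breed with allele frequencies
`p_A = (1-d) p0 + d`, `p_B = (1-d) p0` (`p0 ~ Beta(2,2)` per SNP,
divergence d = 0.6 by default; d = 1 fixes the breeds for alternate
alleles), then gametes dropped through the pedigree with Haldane
recombination — the source haplotype follows a Markov chain switching
between adjacent markers with `r = (1 - e^{-2d})/2`, exact under no
interference. Default map: 5 chromosomes x 40 evenly spaced SNPs over 1
Morgan, 1 cM ~ 1 Mb. This reproduces the long-range LD of an F2 cross
(verified: mean adjacent-pair r^2 decays across map-distance bins; fully
divergent founders give all-heterozygous F1 and 1:2:1 F2 segregation).

Expression is generated from the same sire-dam model the pipeline fits:
cyclic season effects (N(0, 0.5^2) per level per transcript), a common
age slope (0.002 log2-units/day), parental additive effects drawn with
covariance `sigma2_a * A_par` (defaults 0.25 / 0.75 for a polygenic h2 of
0.25; recovery tests use 1/1), planted per-allele eQTL effects, and
residuals from one of four shape families — normal, shifted lognormal
(right skew), Student t3 (heavy tails), uniform (short tails) — each
analytically centered and scaled so the residual variance is exactly
sigma2_e. The default `residual_family="mixed"` cycles the four families
across transcripts (recorded in the truth table) to exercise every branch
of the adaptive test. Planted effects have fixed magnitude
`effect_size_sd` with random sign, so a stated effect size is the literal
per-allele shift rather than the SD of a random draw. A cis eQTL uses the
SNP nearest its gene's start on the same chromosome; a trans eQTL a
random SNP from another chromosome.

What the simulator does *not* emulate: realistic bovine marker maps or
assembly coordinates, genotyping error, array-level artifacts (probe
effects, batch structure beyond the season classes), LD between planted
and background polygenic variation, mutation, selection, or sex
chromosomes. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed generative model, not robustness
to array-specific artifacts.

## Validation sizes and numerical choices

Test problem sizes are chosen to exercise the claims at meaningful
precision while staying desk-scale: 10,000 null replicates per residual
family for the level check (3 binomial SE = 0.0065 at alpha = 0.05),
1,000 replicates for the power comparison, 500 transcripts (two seeds)
for variance-component recovery, four replicate datasets of a 100-SNP x
100-transcript scan for planted-eQTL recovery and realized FDR, and 10^5
gene-dropping replicates for the kinship oracle. In the FDR accounting a
discovery is counted true when it tags a planted transcript through a SNP
whose empirical r^2 with the causal SNP exceeds 0.05 — an F2 cross has
long-range LD, so neighbouring markers of a true signal are hits, not
false positives; everything else counts false.

Numerical conventions: eigenvalues of A and K clipped at zero (PSD up to
round-off); REML tolerance 1e-8 on lambda; ties broken by mergesort
(stable) everywhere ordering matters; all randomness through
`numpy.random.default_rng` with explicit seeds; scan output is
deterministic given inputs.

## Known limitations

- The selector cutoffs and trimming proportions are standard but not
  canonical; they are config, not constants, and the chosen test is
  recorded per association so a re-tuned table can be compared.
- The chi-squared null is asymptotic; at n below ~20 per test use the
  permutation mode.
- BLUP standard errors, dominance, multi-trait models and genomic
  (marker-based) kinship are out of scope — the pipeline deliberately
  uses pedigree kinship only.
- `equivalent_fdr` and `threshold_from_rejections` are exact only under
  the BH step-up bookkeeping they mirror; they are reporting aids, not
  inferential procedures.
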