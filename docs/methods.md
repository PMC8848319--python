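# Methods

## Model and procedure

The pipeline tests for statistical epistasis — departure from additivity of
two loci's effects — restricted to gene pairs with prior co-function
evidence. The unit of inference is the *gene model* (an unordered gene pair
from the knowledge network with evidence from at least `min_evidence` = 2
sources, self-pairs removed). Each gene model is expanded into *SNP models*:
all unordered pairs (a, b) with a mapped to one gene and b to the other
through the union of the requested SNP-gene mapping sources (positional,
eQTL, chromatin; optionally restricted to tissues). A SNP pair induced by
several gene models is tested once and contributes to each parent.

The phenotype is binary case/control. Population structure is removed once,
up front, by logistic regression of the phenotype on the covariates
(iteratively reweighted least squares, gradient norm ≤ 1e-8 or 100
iterations); the working phenotype is the response residual y − p̂. The
per-pair test is ordinary least squares of this residual on
[1, g_A, g_B, g_A·g_B] with a two-sided Student-t test (residual degrees of
freedom) on the product coefficient. The t reference rather than a normal
approximation keeps the test exact at the small sample sizes used in unit
tests; the difference is negligible at cohort scale. Samples missing either
genotype are dropped for that pair only. Rank-deficient pair designs (e.g.
no heterozygotes among minor-allele carriers) are flagged degenerate and
recorded with p = 1. p-values are clamped to the smallest positive float,
never 0.

### SNP-model quality control

Per SNP (pooled cases+controls): minor allele frequency = folded mean
dosage / 2 over complete cases; Hardy–Weinberg exact test conditioning on
allele counts, summing the probabilities of all heterozygote counts no more
probable than the observed one. A pair is dropped when either member has
MAF strictly below 0.05 or HWE p strictly below 0.001 (whitelisted SNPs are
exempt from these two rules only), when both members fall inside the closed
HLA interval (configurable; chr6:25,000,000–34,000,000 in GRCh37
coordinates is the conventional window), or when the dosage-correlation
(composite) LD r² strictly exceeds 0.75. Pairs whose LD is undefined
because a member is monomorphic are kept and flagged. QC depends only on
genotypes, so permutation stages never recompute it.

### Family-wise error control at the SNP level

The adjusted phenotype is permuted `n_perm` = 400 times with a seeded
generator; each permutation is scanned over all QC-passed SNP models and
the minimum p recorded. The significance threshold is the
floor(level·n_perm)-th smallest minimum (k = 20 at defaults — the 5%
percentile of the min-p null). "Percentile" is not pinned to an
interpolation rule, so the k-th order statistic was chosen; with fresh null
data this yields P(min-p ≤ threshold) = k/(n_perm+1) ≈ level. When
level·n_perm < 1 the smallest minimum is used and a warning raised.

### Gene-level aggregation (adaptive truncated product method)

For each gene model parenting ≥ 1 significant SNP pair, the statistic at
truncation point τ is W(τ) = ∏ᵢ pᵢ^{I(pᵢ ≤ τ)} (empty product = 1),
computed in log space. One shared set of B = 999 seeded permutations of the
adjusted phenotype is scanned once for the SNP models of all candidate gene
pairs; sharing preserves the dependence between gene models and costs B
scans in total. P-values above the storage threshold (max τ = 0.05) are
stored as absent, which is exact for every W(τ) used. Following the
convention that the observed dataset takes part in its own null reference,
π_b(τ) = #{l = 0..B : W_b(τ) ≥ W_l(τ)}/(B+1) with inclusive comparison,
π*_b = min_τ π_b(τ), and P₀ = #{l : π*₀ ≥ π*_l}/(B+1); the gene model is
significant iff P₀ ≤ α = 0.05. All π and P₀ values lie on the grid
{j/(B+1)}, so under an exchangeable null P(P₀ ≤ α) = floor(α(B+1))/(B+1) —
exactly 0.05 at B = 999. The storage threshold default (0.05 rather than
the 1e-4 a PLINK-based scan would keep) is a deliberate choice so that
W(0.01) and W(0.05) are computed exactly rather than from a truncated
record.

Permutations act on the adjusted phenotype vector, not on the raw binary
phenotype with re-adjustment: this breaks every genotype-phenotype
association while preserving the residual distribution, and makes the
permuted and observed scans directly comparable.

### Polygenic-score diagnostics

Single-SNP association of every SNP with the adjusted phenotype feeds a
greedy clumping pass (±250 kb, p ≤ 1, r² > 0.1; ties in p broken by
position then id), and the PRS is the average of β·dosage over the kept
SNPs with non-missing genotypes per sample. Significant pairs are re-tested
with the PRS appended to the design (β₄ term). The adjusted p-values are
descriptive: inference keeps the unadjusted ones, the diagnostic flags pairs
whose signal collapses once main effects are absorbed (phantom epistasis).
The single inclusion threshold p ≤ 1 replaces a high-resolution threshold
search: the score's only role here is to absorb all additive main effects.

### Pathway stage

The neighborhood of a significant gene pair (A, B) is built on the
unweighted graph of all filtered gene models: remove the direct A–B edge;
a node v lies on a shortest path iff d(A,v) + d(v,B) = d(A,B); intermediate
nodes are kept only if they form a significant gene pair with another node
on those paths (the partner may be an endpoint); A and B are always
members. Neighborhoods with ≥ 3 members are tested. Enrichment in a gene
set is the exact hypergeometric upper tail P(X ≥ k) with the universe
restricted to annotated genes mappable to a dataset SNP (and, outside the
standard mode, present in ≥ 1 gene model). The Bonferroni denominator is
(#sets touched by any tested neighborhood) × (#tested neighborhoods) with
one shared threshold — the global reading of an ambiguous rule; a
per-neighborhood variant is switchable by configuration. Significance is
strict (p < threshold). An optional set-size filter (e.g. 10–500) is off by
default.

## Synthetic data

The generator emulates the structure of a case-control interaction study:
per LD block, a latent Gaussian with exchangeable correlation is thresholded
at the allele-frequency quantile twice per sample and summed, giving 0/1/2
dosages in Hardy–Weinberg proportions marginally with tunable within-block
LD and independence across blocks. Genes tile the SNP axis; the network is
a uniform random edge set containing all planted pairs (planted edges are
forced to evidence ≥ 2 so they survive filtering); evidence counts are
drawn from a configurable distribution over {2, 3} by default. The
phenotype follows a logistic model with optional additive main effects,
planted gene-pair interactions — each carried by exactly one representative
SNP pair (the first mapped SNP of each gene), matching the observation that
significant gene-level interactions are typically supported by few SNP
pairs and simplifying power accounting — and a standard-normal latent
ancestry axis exposed directly as a covariate (standing in for principal
components; computing PCs from genotypes is out of scope).

The defaults (500 samples, 200 SNPs in blocks of 5 at latent correlation
0.3, MAF uniform on [0.1, 0.5], 40 genes × 5 SNPs, 60 edges, no effects)
describe a desk-scale null study. What the simulator does **not** reproduce:
realistic recombination maps and LD decay, allele-frequency spectra, case
ascertainment, genotyping error/missingness patterns, or real co-function
network topology. Passing calibration tests therefore demonstrates the
statistical machinery is correct under the stated generative model, not
that real-data results at biobank scale would be identical.

## Calibration experiments

`scripts/acceptance.py` runs three experiments at desk scale (sizes chosen
as a compromise between Monte-Carlo error and a quick single-CPU run):

* **t1** — type I error of the full cascade: null dataset (n = 500, 200
  SNPs, 60 gene models), threshold from 200 permutations, 200 outer
  phenotype permutations each rerun through scan → selection → ATPM
  (B = 199). Reported as #FP/200 in percent. With a 200-permutation
  threshold the estimate has a standard deviation of roughly 2 percentage
  points around its ~5% mean, which the binomial CI reported alongside
  reflects.
* **t2** — achieved FWER of the permutation threshold: 50 SNP models,
  threshold from 400 permutations, evaluated on 400 fresh independent null
  phenotype draws; the expected value is k/(n_perm+1) = 20/401 ≈ 5%.
* **t3** — ATPM null rejection rate without preselection: 1000 replicates,
  each one gene model with N = 4 SNP models at n = 300, B = 999; the
  theoretical rate is exactly 0.05 on the permutation grid.

## Numerical choices and edge cases

* Missing genotypes use a dedicated −1 sentinel; every operation either
  declares complete-case handling or refuses missing input.
* All W computations run in log space; the empty product is log W = 0.
* Tie handling follows the printed inclusive inequalities everywhere:
  p ≤ τ in the truncation, ≥ in both permutation indicator sums,
  p ≤ threshold for SNP-level significance, P₀ ≤ α at the gene level,
  strict < for the pathway Bonferroni rule, strict inequalities for the QC
  drops (MAF <, HWE p <, r² >).
* Monomorphic SNPs: MAF 0 (dropped by QC), HWE p = 1, undefined single-SNP
  association (flagged), undefined LD (pair kept and flagged).
* All randomness derives from one master seed through fixed per-stage
  counters (`SeedSequence([master, counter])`), recorded in the config
  snapshot; runs are reproducible byte for byte.

## Known limitations

* Only biallelic, unphased, integer-dosage genotypes (PLINK 1 binary);
  no VCF/BGEN, no dosage uncertainty, no X-chromosome handling.
* Within-gene epistasis is excluded by construction.
* The logistic-residual linear-model approximation is inherited from the
  protocol; a full logistic interaction model with covariates would be more
  principled but is deliberately out of scope.
* The type-I harness reuses the observed-data threshold across outer
  permutations rather than nesting 400 fresh threshold permutations inside
  each: under the global null the two distributions coincide, and nesting
  would multiply cost by the permutation count.
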