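# Methods

This note documents the statistical models, numerical choices and synthetic
data conditions behind `strhab`, in the spirit of a model-documentation page
for a simulation/analysis package.

## Tract detection and coordinates

A homopolymer tract is a maximal run of codons translating to the same
amino acid (stop codons excluded). With `merge_synonymous=True` (default)
adjacent perfect runs of synonymous codons (e.g. CAA/CAG) merge into one
tract; with the flag off only literally identical codon runs count. Only
codon-aligned repeats are considered, because off-frame trinucleotide
repeats do not encode homopolymers. The detection floor is 4 repeated
residues (`min_units=4`), the conventional threshold for calling a coding
STR. Detection is exact and deterministic — no alignment score heuristics —
so it is testable against an O(n²) brute-force oracle; the trade-off is
that imperfect (interrupted) repeats are not merged across the
interruption.

Coordinate conventions: nucleotide intervals are 0-based half-open (BED),
residue intervals 1-based inclusive; conversions live in one place
(`GeneModel.cds_to_genomic` / `genomic_to_cds`), are exact per base, and
round-trip as identities, including for tracts spanning introns (the
reported genomic interval is the spanning interval).

Tract×track overlap uses "≥1 shared residue" for binary features (no
minimum-overlap fraction is imposed), while residue-level intersection
counts are retained for enrichment tables. The per-residue disorder
consensus follows the ≥⌈0.75·n_tools⌉ agreement rule used by consensus
disorder databases.

## Enrichment

For an amino acid and a region track the 2×2 table partitions the residue
universe (all residues of all input proteins by default; a flag restricts
to proteins carrying ≥1 tract): A = STR-encoded residues in the region,
B = non-STR residues in the region, C = STR-encoded outside, D = non-STR
outside. The odds ratio is the cross-ratio AD/BC; p-values come from the
exact hypergeometric distribution (two-sided: summing all tables with the
same margins that are as or less probable). No continuity correction is
applied to zero cells; odds ratios of 0/∞ are reported as such with finite
p. The Bonferroni family is every (amino acid × region) test of one
invocation.

## Environmental space

Variables are complete-case filtered (columns with any missing value
dropped), standardized to zero mean and unit variance (population scaling,
ddof=0), and decomposed by SVD. Retention rules: `cumulative:f` keeps the
smallest axis prefix whose explained fractions reach `f` (e.g. 0.8);
`per_axis_min:f` keeps every axis explaining more than `f` (e.g. 0.01,
used for subpopulation-mean decompositions). Axis signs are fixed so the
variable with the largest |loading| loads positively, making output
reproducible across SVD implementations. The confounding diagnostic
regresses each environmental axis on the top two principal axes of the
kinship matrix and reports R² with the F-test p.

## Association scan

For each locus and axis the environmental axis is the response (the
direction matters only for the R²/p bookkeeping; the test is symmetric):

- continuous encoding: diploid unit-count sum of the two alleles;
- categorical encoding: unordered allele-pair label. Singleton genotype
  classes are merged into the nearest class by unit-count-sum distance
  (ties toward the smaller label) to prevent saturated fits.

Biallelic loci (≤2 classes) are reported as `linear` (the two fits
coincide). For multiallelic loci the models are compared by the nested
F-test at α=0.05 and the better model's R² and p are kept. The fits use
closed-form least-squares arithmetic (simple regression and group means);
a unit test verifies exact agreement with statsmodels `ols`/`anova_lm`.
Bonferroni correction runs over all (locus × axis) tests of a scan with
the strict rule `p·m < α`. Mock scans permute genotype rows independently
per locus; both the all-tests and best-per-locus significant fractions are
reported, since either tally is a defensible summary.

Note that keeping the better of two nested models perturbs the selected
p-value distribution slightly even under the null; the mock-scan
uniformity test uses a Kolmogorov–Smirnov bound of 0.08 to allow for this
known effect while still catching real miscalibration (structure-
confounded scans sit near 0.35–0.4).

### Mixed model

The LMM uses covariance σ²g·K + σ²e·I with the environmental axis as
response and the continuous genotype encoding as the fixed effect of
interest. Variance components are estimated by maximum likelihood (not
REML) for both the null and the genotype model so the likelihood-ratio
statistic is coherent; p = χ²(df=1) survival of the LRT. One
eigendecomposition of K is shared across all loci and axes (missing calls
trigger a per-locus re-decomposition of the subset matrix); the 1-D profile
likelihood in the variance ratio δ = σ²e/σ²g is maximized by bounded
scalar minimization on log δ ∈ [−10, 10]. At K = I the χ² LRT differs
from the exact OLS F-test only by an O(1/n) term (<0.01 on the p scale at
n=100). Non-PSD kinship inputs are clipped to the nearest PSD matrix with
a warning.

Kinship is computed from biallelic SNP dosages: major-allele-frequency
filter (<0.9), windowed greedy LD pruning, then Pearson correlation
between accessions *after centering each SNP by its mean dosage* —
without the per-SNP centering the shared allele-frequency profile induces
a large constant correlation that swamps the structure signal. The matrix
is standardized to unit diagonal. Centered correlations sum to ≈0 per
row, so the expected off-diagonal under no structure is −1/(n−1), not 0.

## Population-genetic scans

Allele frequencies are tallied per locus and subpopulation (chromosome
counts = 2 × non-missing calls). Biallelization defines the major allele
globally per locus by pooled chromosome counts (ties toward the smaller
unit count) and pools the remainder. Pairwise Hudson F_ST uses

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

with NaN when both populations are fixed for the same allele; negative
values are retained (they carry information for the percentile pool). The
per-locus summary is the mean over defined pairs; outliers are summaries
above the 95th percentile of the summary pool.

LD pruning is the standard windowed greedy filter (drop a column whose r²
with an earlier retained column in the window exceeds the threshold;
advance by `step`); zero-variance columns are dropped up front. Defaults
mirror common practice for SNPs (size 1000, step 20, r² 0.1) and for STR
frequency profiles (size 10, step 1, r² 0.1). With ~10 subpopulations the
expected r² between two random frequency profiles is ≈1/9, so a 0.1
threshold on *global* windows would prune nearly everything — windowed
pruning is not just cheaper, it is what keeps enough loci to estimate the
structure covariance.

### Bayes factors

The environmental Bayes factor is an analytic, conjugate stand-in for an
MCMC-based covariance-aware association model: exact per-locus allele
frequency MCMC is out of scope, but the model family is the same. Per
locus, subpopulation frequencies are transformed to x_s = arcsin(√p_s)
(approximately variance-stabilizing for binomial sampling). The null is
x ~ MVN(μ·1, τ²Ω) with Ω the subpop×subpop covariance estimated from the
transformed frequencies of an LD-pruned locus set, and (μ, τ²) profiled in
closed form. The alternative adds a mean shift βE (E the environmental
axis standardized across subpopulations) with conjugate prior
β ~ N(0, prior_sd²·τ²); marginalizing β gives
x ~ MVN(μ·1, τ²(Ω + prior_sd²·E·Eᵀ)), and (μ, τ²) are profiled under this
model too. The reported log₁₀ BF is the profile marginal-likelihood
ratio. Two exact properties follow: prior_sd → 0 collapses the BF to 1
for every locus, and a constant environmental axis gives BF = 1. The
prior scale (default prior_sd = 1.0) multiplies τ², making the prior
scale-free. Profiling τ² under *both* models matters: plugging the
null-profiled τ² into the alternative dilutes the likelihood gain by the
signal-inflated null scale and destroys power. Singular Ω inputs are
ridge-regularized with a warning. `estimate_covariance` optionally trims
the most deviant loci (one-step Mahalanobis trim) before re-estimating —
a lightweight robustness option against selected-locus contamination; the
default is the plain sample covariance.

### Overlap permutation test

Observed overlap of the three candidate sets (default rule: loci present
in all three; `at_least_two` available) is compared against a null built
by redrawing each set at its observed size uniformly without replacement;
the empirical p uses add-one smoothing. The null mean matches the
closed-form expectation N·∏(k_i/N) for independent draws.

## Meta-regression

Per-locus responses: association R² of the best record (min-p selector by
default; max-R² available), maximum log₁₀ BF across axes, mean F_ST. Each
is regressed on amino acid (one-hot against an alanine baseline;
lexicographic fallback when alanine is absent), the ordinal 0–3
protein-binding agreement, and binary DNA-binding, RNA-binding and
disorder indicators. Plain OLS t-scores are reported (no robust standard
errors, mirroring the basic formula fit); the Bonferroni threshold is
0.05 divided by the number of non-intercept coefficients actually in the
design, recomputed per fit rather than hard-coded. Constant columns are
dropped before fitting.

## Synthetic cohorts

The generator defines the study conditions for all tests; its defaults
describe a 200-accession, 10-subpopulation cohort with 300 multiallelic
STR loci, 1000 block-LD SNPs and 88 environmental variables.

- **STR alleles.** Per locus, a global reference length (8–14 units,
  drawn away from the 4-unit detection floor so effect shifts stay in the
  dynamic range), subpopulation means from a truncated normal with scale
  `drift_scale`, and individual alleles = rounded subpop mean ±
  (geometric(p=0.5) − 1) mutation steps, truncated to [4, 40] units. Two
  alleles per accession are drawn independently (no selfing model).
- **Divergent loci** (F_ST ground truth) are two-allele loci whose high
  allele frequency is U-shaped (Beta(1/s, 1/s)) across subpopulations —
  near-fixed differences, the textbook strong-divergence signal. A
  continuous inflated-drift model was rejected because biallelization of
  highly multiallelic drifted loci already yields high F_ST, leaving too
  little contrast.
- **Environment.** Seven latent factors; each is
  c·u_subpop + √(1−c²)·noise with confounding weight `confound_strength`.
  The subpopulation components of distinct factors are orthogonalized
  (QR), since with 10 subpopulations two random gradient vectors are
  often correlated by chance, which makes principal axes unidentifiable —
  orthogonal contrasts are what a PCA can in principle recover. Observed
  variables load on one factor each, with geometrically decaying variable
  counts and loading strengths (`factor_decay`, default 0.6) so the
  leading axes dominate the spectrum, as leading climatic gradients do in
  real bioclimatic panels.
- **Planted effects.** `linear`: allele unit counts shift by β·F with
  stochastic rounding, so E[units|F] is exactly linear. Note the scan
  regresses the *reverse* conditional E[F|units], which is inherently
  mildly sigmoidal for a discrete forward shift — the nested F-test
  therefore correctly prefers the categorical model in roughly 10% of
  strong-effect replicates; recovery tests assert ≥90% detection and ≥80%
  correct model class. `threshold`: the factor responds to a genotype
  step (units above the cohort median), planting a genuinely nonlinear
  conditional mean over overlapping genotype support; a unit-count shift
  by a binary environmental split was rejected because it produces two
  tight genotype clusters whose step relation is almost perfectly linear.
  `cline`: a two-allele mixture whose high-allele probability follows the
  factor logistically — the canonical signal for allele-frequency /
  environment scans; mean-shift planting cannot create a monotone
  major-allele-frequency gradient (subpopulations shifted in either
  direction both lose the central major allele).
- **SNPs.** Balding–Nichols subpopulation frequencies
  (θ = 0.1·drift_scale) at a per-block anchor; within a block of 20 SNPs
  each marker copies the anchor haplotype with a per-SNP flip probability,
  giving realistic within-block LD decay.
- **Annotation tracks.** Per-residue Bernoulli tracks; residues inside
  tracts are included at odds inflated by the planted log OR. Background
  rates are deliberately sparse (IDR 0.05, binding tracks 0.02–0.03) so
  the *tract-level* ≥1-residue overlap fractions stay moderate; real IDRs
  are long contiguous segments, which the residue-independent model does
  not emulate — passing tests therefore validate the counting and
  inference machinery, not the spatial statistics of real disorder
  annotations.
- **Missingness** is an optional uniform mask (default 0); the real
  cohort's missing-call structure is not asserted.

What the synthetic conditions do **not** emulate: coalescent ancestry,
recombination maps, selfing/inbreeding, mutation-rate heterogeneity,
genotyping error from read data, spatially autocorrelated environments,
and contiguous disorder segments. Results on synthetic cohorts validate
correctness and calibration of the statistics, not effect sizes expected
in real data.

## Problem sizes and determinism

The test suite runs its recovery studies at 50 replicates of small cohorts
(120 accessions × 15–40 loci) and its calibration checks at 200×300; the
acceptance script uses ten 200×300 cohorts. All randomness flows through
`numpy.random.default_rng` seeded from explicit arguments; identical
seeds reproduce byte-identical outputs, and the pipeline manifest records
seeds and SHA-256 digests of every stage output.
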