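# strhab

Environmental association analysis of protein-coding short tandem repeats
(STRs).

Coding STRs with a three-nucleotide unit encode **homopolymer tracts** —
runs of identical amino acids whose lengths change rapidly through DNA
replication slippage. Such tracts accumulate in intrinsically disordered
protein regions (IDRs) and predicted disordered binding sites, and their
length variation across a large, geographically structured cohort of
resequenced plant accessions can be tested for association with the local
bioclimatic habitat. `strhab` implements that analysis as a reusable,
fully testable pipeline:

- **tracts** — detect maximal in-frame trinucleotide repeats in CDS FASTA
  (detection floor: 4 repeated residues), map them between CDS, protein and
  genomic coordinates (GFF3 gene models, spliced tracts included), and
  intersect them with per-residue annotation tracks (IDR; three
  protein-binding predictors combined into an ordinal 0–3 agreement score;
  DNA- and RNA-binding).
- **enrich** — 2×2 contingency tables over the residue universe
  (A = STR-encoded residues inside the region, …); odds ratio AD/BC with
  two-sided (or one-sided) Fisher exact p-values and Bonferroni control.
- **envspace** — complete-case filtering, standardization and SVD
  decomposition of bioclimatic variables with two retention rules
  (smallest axis prefix reaching a cumulative explained-variance target;
  all axes above a per-axis minimum), plus a structure↔environment
  confounding diagnostic (environment regressed on the top two kinship
  axes).
- **assoc** — per (locus × axis) ordinary least squares with the
  environmental axis as response and the STR genotype as predictor, in two
  encodings: continuous (diploid unit-count sum) and categorical (unordered
  allele-pair label, capturing nonlinear length effects). Multiallelic loci
  keep the better model by a nested F-test. Mock scans (per-locus shuffling
  of genotypes among accessions) give the negative control; a maximum-
  likelihood linear mixed model with kinship covariance σ²g·K + σ²e·I
  re-tests associations under population structure (χ² likelihood-ratio
  p-values, one eigendecomposition of K reused across loci).
- **popgen** — per-subpopulation allele frequencies, biallelization
  (global major allele vs. pooled remainder), pairwise Hudson F_ST over all
  45 subpopulation pairs with 95th-percentile outlier calling, windowed
  greedy LD pruning, an analytic covariance-aware Bayes factor for
  allele-frequency/environment gradients (MVN on arcsine-square-root
  frequencies, conjugate Gaussian effect prior), and a candidate-set
  overlap permutation test (draws without replacement).
- **metareg** — regress per-locus association strength (best R², max
  log₁₀ BF, mean F_ST) on tract features (amino acid vs. alanine baseline,
  disorder, binding propensities) with plain OLS t-scores and a Bonferroni
  threshold recomputed from the coefficient count.
- **synth** — a first-class synthetic-data generator producing full
  cohorts with known ground truth: ~10 subpopulations with hierarchical
  drift, multiallelic stepwise-mutation STR genotypes, block-LD neutral
  SNPs, structure-confounded environmental variables, planted
  genotype-environment effects (linear, threshold, and allele-frequency
  cline shapes), and annotation tracks with planted enrichment.

## Worked example

`examples/` contains one short script per capability. For instance the
association scan (`python examples/04_association_scan.py`) plants one
linear tract-length effect in a 150-accession cohort and prints:

```
120 tests (30 loci x 4 axes); 1 Bonferroni-significant
planted locus L0010: best axis PC2, model categorical, R^2 = 0.698, p = 3.44e-18, significant = True
mock control (shuffled genotypes): 0.00% significant
```

The planted locus is the single Bonferroni-significant hit (R² is the
variance of the environmental axis explained by tract length; the nested
F-test chooses between the linear and categorical genotype encodings),
while the same scan on shuffled genotypes finds nothing. The
meta-regression example (`06_meta_regression.py`) reproduces the
qualitative "three of three" pattern: when disordered poly-Q/poly-N tracts
carry planted environmental clines, the Q, N and disorder coefficients are
positive and Bonferroni-significant for all three responses (R², Bayes
factor, F_ST).

A thin command-line interface wraps the same library calls:

```bash
strhab run --out demo_run --seed 5        # full synthetic pipeline + manifest
strhab tracts --cds cds.fa --out tracts.bed
strhab envpca --env env.tsv --rule cumulative:0.8 --out envpca/
strhab assoc --geno genotypes.tsv --scores envpca/scores.tsv --out assoc.tsv
strhab fst --geno genotypes.tsv --subpops subpops.tsv --out fst.tsv
```

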