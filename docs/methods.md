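# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `rnaqtl`.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Setting and assumptions

The package assumes genotypes were derived from RNA-seq reads (per-sample
calling followed by imputation), which has three consequences the methods
are built around:

1. Genotype and expression data come from the same reads, so a gene that is
   not expressed yields no genotype.  Permutation nulls must therefore
   preserve the expression context of each sample — permutations are
   restricted to within-study swaps (studies are treated as single-tissue).
2. Imputed dosages are noisy; their quality is summarized per variant by
   DR2, the estimated squared correlation between imputed dosage and the
   true genotype.  Association uses dosage; hard-call analyses
   (deduplication, heterozygosity, ASE het status) use direct calls gated
   by genotype quality (GQ).
3. Cohorts assembled from public data contain duplicates, contaminated
   libraries, mislabeled sexes and strong study/tissue structure; QC stages
   target each of these explicitly.

## Models and procedures

### Heterozygosity screen

Per sample, the fraction of heterozygous calls among non-missing calls at
sites with MAF ≥ 0.05 and per-sample depth ≥ 10 reads.  Samples with fewer
than 50 qualifying sites are reported as unknown rather than given an
unstable estimate (a binomial SE below ~0.07 at the boundary).  Bounds
0.2/0.4 are exclusive.  A 1:1 pooled library is called heterozygous
wherever its two source genomes jointly carry both alleles, which pushes
the rate to ≈ 0.5 under any common-variant spectrum — well above 0.4.

### Expression-outlier rule

The upstream practice of eyeballing the first principal component is made
reproducible: robust z = (score − median)/(1.4826·MAD) on a configurable
component, flag |z| > 4.  When the MAD is zero, any deviation from the
median is treated as infinite z (so a constant cohort flags nothing, but a
few shifted samples among identical ones are flagged).

### Duplicate detection

Hard-call concordance is computed over jointly non-missing, LD-pruned,
high-quality variants.  Two added safeguards the source procedure leaves
implicit: pairs with fewer than 100 comparable sites are reported unknown
(never merged), and the ≥ 0.78 graph is resolved into connected components
— identity is treated as an equivalence relation.  During pruning, of an
r²-violating pair the lower-MAF variant is dropped (tie → later position),
keeping the more informative variant.

### Normalization chain

TMM follows the published trimmed-mean-of-M-values definition: reference =
sample whose upper-quartile (of library-size-scaled counts) is closest to
the mean; per sample, gene-wise log2 ratios M and abundances A over genes
nonzero in both; 30% trimmed from each tail of M and 5% from each tail of
A; factor = 2^(precision-weighted mean of surviving M), with delta-method
precision weights; factors normalized to geometric mean 1.  Counts are then
scaled by library size × TMM factor, log2(x + 1)-transformed, and each gene
is centered and scaled.  Covariates (log library size and the leading
genotype PCs) are removed by per-gene OLS; expression PCs are then computed
on the corrected matrix and projected out.

The number of removed expression PCs defaults to `min(100, n_samples/10)`.
The full-cohort correction used 100 components on ~1,250 samples (≈ n/12.5),
so n/10 preserves that ratio at desk scale; removing n/4 components was
measurably destructive to planted signals in cohorts of a few hundred
samples.  The full-cohort value (100) is available by configuration.

Quantile normalization assigns each rank the cross-sample mean of sorted
values; ties receive the mean of the quantile values they span.  With the
tie rule, exact idempotency and exactly shared sorted profiles hold on
tie-free data (continuous values); tied counts are handled deterministically
but can shift the shared profile by the within-tie averaging.

### cis-eQTL mapping

The association statistic is Spearman's ρ (rank robustness across
heterogeneous samples), converted through the t approximation
t = ρ√((n−2)/(1−ρ²)) to a two-sided p and a signed z.  Populations are
analyzed separately (minimum 30 samples to enter) and combined by
sample-size-weighted z: `meta_z = Σ z_k √n_k / √Σ n_k`.  Weighting by √n
rather than by estimated precision was chosen because rank-based z-scores
carry no natural per-study variance estimate; it is exact for equal
per-sample information.

Gene-level significance: each gene's best cis p-value is compared with the
same quantity under permutations of the expression↔genotype linkage within
studies.  FDR(t) = (mean permutation count of genes with best-p ≤ t) /
(observed count with best-p ≤ t), clipped to [0, 1] and monotonized
(running maximum in t).  Using the best-variant p against a best-variant
null self-corrects for per-gene multiplicity.  Ties for "top variant" break
by smallest p, then smallest distance, then variant id.  The default of 10
permutations estimates the null counts adequately because the null is
pooled across all genes.

Replication of result set A in result set B tests, for each A-significant
gene, its top variant's p-value in B against B's own significance region
(the largest best-p among B's significant genes); direction concordance is
the sign agreement of meta_z among replicated pairs.  The ASE↔eQTL
direction comparison uses the same pair-level significance rule: a SNP
counts only if it shows a significant eQTL effect on the gene, not merely
lies cis to a significant gene.

### ASE

A single shared alt-fraction p per SNP across het carriers (pooled
binomial): the MLE is closed-form and the likelihood-ratio statistic
depends only on pooled counts, so any partition of the same pooled counts
gives the identical statistic (this invariance is tested exactly).
Overdispersion across carriers (beta-binomial) is deliberately out of
scope.  The read-count filters ("≥ 10 reads per allele", "≥ 2% of all
reads per allele") are applied to pooled counts by default, matching the
pooled test; per-sample semantics are available by flag.  Base-quality
filtering of reads is assumed done upstream when the count table was
produced.  Reference bias is diagnosable (mean p̂ at null sites) but not
corrected; the upstream remedy is genome masking before alignment, which is
outside this package.

## The synthetic-data generator

The generator produces caller/imputation *outputs*, not reads.  Defaults
are one desk-scale study configuration chosen once: 127 base samples in
population proportions EUR:AFR:ASN ≈ 8:1.7:1, four single-tissue studies
(the first flagged as the reference set), 500 genes and 1,500 variants on a
10 Mb chromosome, mean depth 30, 10% of genes with a planted cis effect of
1 noise-SD per alt allele, 5% of sites with planted allelic ratio 0.7, two
duplicate pairs and one contaminated mixture.

- **Allele frequencies** follow a Balding–Nichols model: ancestral MAF with
  density ∝ 1/f on [0.05, 0.5] (neutral-spectrum-like), per-population Beta
  drift at Fst 0.1.  This separates populations in genotype PCA while
  keeping common variants common across ancestries, as shared ancestral
  polymorphism does.  Under this spectrum clean-sample heterozygosity is
  ≈ 0.27 (inside the 0.2–0.4 QC band) and 1:1 mixtures land near 0.5.
- **Dosage noise** is truncated Gaussian, calibrated per (variant,
  population) by a short fixed-point iteration so the realized corr²(dosage,
  truth) matches the target DR2 despite truncation to [0, 2].  Calibration
  is within-population because imputation accuracy is an ancestry-specific
  property (reference-panel match); the stored DR2 equals the target.  The
  adjustment is skipped for monomorphic variants and populations under 10
  samples, where the empirical correlation is degenerate.  The default
  target is 0.96 (well-imputed common SNPs), so that a realistic fraction
  of variants survives the strict DR2 > 0.95 deduplication filter;
  experiments that study genotyping accuracy set 0.9 explicitly.
- **Hard calls** are direct-calling emulations: correct with probability
  1 − 10^(−GQ/10), GQ = min(99, 3·depth), missing at zero depth; depth is
  Gamma–Poisson (per-variant mean from Gamma(2, depth/2)), so sparse sites
  get low GQ and are removed by the GQ > 30 ASE gate.  The noise-free
  configuration (DR2 = 1) disables all genotyping noise.
- **Expression** is log-linear: gene baseline + per-(study, gene) offset
  (SD 0.5) + library-size and GC×library terms + β·σ_ε·(true dosage) for
  planted genes + Gaussian noise (σ_ε = 0.5), exponentiated and
  Poisson-sampled.  Genes are anchored at variants so every planted gene has
  a cis variant within 250 kb.  Planted effects are placed at anchors with
  cohort MAF ≥ 0.2: an effect stated in SD-per-allele is only a comparable
  effect size at comparable frequency, and cis-eQTL power analyses plant at
  common variants.  Sex marker genes (XIST and three chrY genes) are
  appended with expression tied to each sample's true sex.
- **Allelic counts**: for each called-het (variant, sample), total = that
  cell's read depth, alt ~ Binomial(total, p′) with p = 0.5 (null) or the
  planted ratio, and p′ = (1−b)p / ((1−b)p + (1−p)) under reference bias b.
  2% of non-planted sites are placed in exclusion regions and another 2%
  given mappability 0.5, so the site filters are exercised; the
  corresponding BED tracks are written with the bundle.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: linkage disequilibrium beyond planted duplicates
(pruning is exercised on constructed copied-with-noise blocks), read-level
artifacts (position-specific error, splice-junction alignment bias),
overdispersed allelic counts, multi-tissue effect heterogeneity, relatedness
short of identity, and annotation errors other than missing sex labels.

## Problem sizes in the property benchmarks

The benchmark experiments (tests/test_acceptance.py and
scripts/acceptance.py) use: ~10,400 null ASE sites (36 samples, depth 100)
for calibration; ~40 planted / ~200 null sites for ratio recovery; n = 200
(two populations, two studies), 500 genes with 50 planted effects, 1,000
variants and 10 permutations for eQTL power, averaged over 20 replicates;
100 samples with 5 duplicate pairs over 20 replicates for deduplication;
and a 300-sample cohort split into halves for replication.  These sizes
were chosen to keep every experiment deterministic and desk-scale while
leaving the measured quantities' sampling error well inside the asserted
tolerances.

## Known limitations

- The FDR estimator is a declared design (plug-in permutation ratio with
  monotonization), not a byte-level reproduction of the cited pipeline's
  estimator, which is not restated in the source.
- Replication "significance in B" uses B's gene-level significance region
  rather than refitting a single-variant test in B.
- The GC technical correction enters as sample-level covariates; a
  per-gene GC regression is available but not default (the upstream
  description is ambiguous between the two).
- VCF records without INFO/DR2 carry DR2 = NaN and fail every DR2
  threshold; supply DR2 (or relax the thresholds) for non-Beagle inputs.
- Multi-allelic records are dropped at parse time; analyses are strictly
  biallelic.
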