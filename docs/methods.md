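# Methods

This note documents the statistical model behind `breedgwas`, the synthetic
cohort generator's assumptions and defaults, the numerical conventions, and
the design choices that were genuinely open.

## The association model

Every sample in a breed carries that breed's trait value (breed-level
phenotypes; there is no within-individual phenotype variation). For each SNP
the trait is regressed on minor-allele dosage g ∈ {0, 1, 2} with an
intercept — the additive genotypic model:

    y_i = α + β g_i + ε_i

fitted by OLS over the samples with a called genotype at that SNP (per-SNP
case deletion; no imputation), with the two-sided Wald-t raw P for β = 0.
Because samples within a breed share y while breeds are strongly
differentiated in allele frequency, the effective sample size is closer to
the number of breeds than the number of dogs, and raw P values are severely
anti-conservative. They are therefore only used as a ranking statistic.

### Breed-randomised min-P correction

Family-wise inference uses a max-T (equivalently min-P) permutation scheme
that preserves the breed-block structure: a permutation draws a uniform
random permutation of the breed → trait-value map (identity included;
the n_perm draws are sampled with replacement from the permutation group, so
duplicate permutations can occur), assigns every sample its permuted breed's
value, re-runs the scan on all SNPs with the original missing-data pattern,
and records the minimum raw P. The corrected P of a SNP with raw P p is

    p_corr = (1 + #{b : min-P(b) ≤ p}) / (n_perm + 1),

with ties counted as exceedances (conservative). p_corr is monotone in p and
lives in [1/(n_perm+1), 1]; with the conventional 1000 permutations the floor
is 1/1001 ≈ 0.000999. Corrected P < 0.05 is "significant", < 0.1 "marginal",
both strict. SNPs monomorphic among their called samples (or with fewer than
3 of them) are reported with raw and corrected P absent (tier `na`).

The per-SNP OLS inside the permutation loop is computed in closed form from
masked cross-products (one pair of matrix products per permutation batch),
which is what makes 1000 permutations over tens of thousands of SNPs cheap;
the tests verify it against `scipy.stats.linregress` fit by fit, and verify
the sampled permutation null against exhaustive enumeration of all 24
assignments in a 4-breed cohort.

A deliberately miscalibrated control (`unit="sample"`: permuting values
across individual dogs, ignoring breeds) is retained for diagnostics; under
breed structure it inflates the family-wise error rate, and a test asserts
the inflation direction.

### Trait residualization

To keep cancer/longevity associations independent of body weight, traits are
residualized before association: cancer mortality on body weight and life
expectancy (multiple regression), life expectancy on body weight (simple
regression). "Standardized residuals" are raw OLS residuals divided by their
sample SD (n−1 denominator), giving mean 0 and SD 1 — not leverage-adjusted
(internally studentized) residuals, which are exposed as an option. The
simpler reading suffices because downstream association is invariant to a
monotone linear transform of the trait. Cancer mortality is also residualized
on weight alone under the separate column `cancer_weight_residual` (the
descriptive-analysis variant), kept distinct to avoid conflation.

The descriptive layer reports Spearman rank correlations (Pearson on
mid-ranks; two-sided P from the t-approximation with n−2 df, appropriate at
n ≈ 63 breeds) and jackknife bias-corrected estimates
n·θ̂ − (n−1)·mean(leave-one-out θ̂). Note a structural property verified in
the tests: for rank correlations the leave-one-out deviations largely cancel,
so the bias-corrected estimate stays close to the plain coefficient even in
the presence of a gross outlier; outlier *influence* is instead visible in
the spread of the leave-one-out estimates (`leave_one_out_spearman`).

## Quality control

Stages in order (order is recorded in the QC report so alternatives can be
compared; the conventional missingness → MAF → HWE → LD order is adopted):

1. **Per-breed cap** (default 30): breeds over the cap are subsampled
   uniformly at random, deterministically per seed.
2. **Autosomes**: chromosome labels 39, X, Y, XY, MT are non-autosomal under
   the dog (CanFam, 38 autosomes) convention.
3. **Missingness** > 0.10 removed.
4. **MAF** < 0.01 removed (minor allele frequency over non-missing
   chromosomes; all-missing SNPs fall out here via missingness = 1).
5. **Hardy–Weinberg** exact conditional test, P < 0.01 removed. The exact
   (not chi-square) test is used because per-breed genotype counts are small;
   probabilities are computed with log-gamma weights and validated against an
   exact-fraction enumeration for every count triple with n ≤ 20. Default is
   a single pooled test across breeds, which under strong differentiation
   also removes SNPs for the Wahlund effect — a stratified per-breed screen
   (`hwe_mode="per_breed"`, removal on the minimum per-breed P) is exposed
   but off by default.
6. **LD pruning**: within-chromosome greedy scan in map order with a
   50-SNP window; of any pair with r² > 0.9 the SNP later in map order is
   removed. r² is the squared Pearson correlation of dosage vectors over
   jointly non-missing samples; undefined pairs (a monomorphic member) are
   skipped with a logged warning.

There is deliberately no sample-level missingness filter and no
relatedness pruning.

Candidate-SNP extraction takes a gene-interval table (gene lists are inputs,
never computed) and returns SNPs within a closed ±20 kb window of any gene
on the same chromosome, each SNP listed once with all gene attributions.
20 kb reflects typical LD decay in pedigree dog breeds; boundary inclusivity
and strand-ignorance are conventions chosen here.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes, not a
biologically detailed dog genome:

* **Between-breed differentiation** follows the Balding–Nichols model: SNP
  ancestral frequency p drawn uniformly from `ancestral_maf_range`
  (default 0.05–0.5); breed frequency ~ Beta with mean p and variance
  F·p(1−p), F = `differentiation` (default 0.2, a strongly structured
  population in line with the high between-breed variance of pedigree dogs).
  Genotypes are binomial within breed.
* **Cohort shape** defaults to 63 breeds × 20 samples (≈1260 dogs), the
  breed count and per-breed cap regime of the across-breed design this
  package targets.
* **Traits** are affine in breed body weight plus Gaussian noise. Defaults:
  weight ~ U(5, 70) kg; life expectancy at age 4 = 13.5 − 0.07·weight +
  N(0, 1.4²) years; cancer mortality = 20 + 0.35·weight + N(0, 11²) percent,
  clamped to [0, 100]. The slopes and noise SDs were chosen once so that the
  breed-level Spearman correlations land in the moderate regime typical of
  published across-breed phenotype data (weight–cancer ≈ +0.5,
  weight–lifespan ≈ −0.7); planted-effect tests avoid the clamped regime.
* **Planted effects** add effect × (breed-mean dosage) to a named trait
  before clamping; the `cancer_residual` / `longevity_residual` trait names
  express the effect in residual-SD units (effect × the trait's noise SD on
  the raw scale), the natural unit for effects meant to survive covariate
  adjustment. Because standardization divides by the realized residual SD
  (which includes the planted genetic variance), the realized standardized
  slope is slightly below nominal (≈1.28 for a nominal 1.5).
* **Missingness** is uniform at random over (sample, SNP) cells (default
  2%); no informative-missingness mechanism is modelled.
* **Duplicated SNPs** (exact copies adjacent in the map) provide perfect-LD
  pairs for pruning tests; there is no other LD structure — SNPs are
  independent, and there is no within-breed pedigree/kinship. One sex
  chromosome (labelled "39") is simulated so the autosome filter has
  something to remove.
* Dosages are reoriented after sampling to count the realized sample minor
  allele (ties at 0.5 resolve to the lexicographically smaller allele),
  matching the PED/MAP reader's convention so write→read round trips are
  exact.

What passing tests on this generator do **not** show about real data:
robustness to LD between candidate SNPs, to within-breed relatedness, to
informative missingness, or to non-affine trait–weight relationships.

## Validation procedures

* **Resampling robustness**: drop floor(0.10·n) samples uniformly at random
  (1274 → 1147 at the reference cohort size), re-run the full
  association + permutation experiment 10 times with the original run's
  permutation seed (so frac = 0 reproduces the original exactly), and count
  per SNP how many repetitions keep its tier.
* **Per-breed MAF scan**: minor-allele orientation is fixed once on the full
  cohort, per-breed frequencies are computed over each breed's called
  genotypes (values may exceed 0.5 within a breed), and each SNP's
  frequencies are correlated with the per-breed trait (Pearson and Spearman,
  pairwise-complete breeds, ≥3 required) with Benjamini–Hochberg q-values
  over all tested SNPs and a lowest-30 ranking report. The trait column is
  an explicit argument — raw or residual traits are both legitimate scans.

## Calibration and power at desk scale

The test suite measures, by simulation: family-wise error of the
breed-block permutation under the global null (20 breeds × 30 samples,
500 SNPs, F = 0.2, 200 permutations, 200 replicates — the fraction of
replicates with any corrected P < 0.05 falls in the binomial band around
5%), and planted-effect recovery. Recovery depends steeply on the number of
breeds: with 63 breeds a 2 residual-SD/dosage-unit effect is top-ranked and
significant in ≈90% of runs, whereas with only 20 breeds the sampling noise
of a breed-level correlation (SD ≈ 1/√19) makes even strong effects
indistinguishable from the maximum over hundreds of null SNPs — a power
limitation of 20-breed designs themselves, demonstrated rather than hidden
by the suite. Problem sizes throughout (SNP counts in the hundreds,
200-permutation nulls in simulation studies, 1000 for single experiments)
were chosen as the smallest scales at which these distributional checks are
stable.

## Numerical conventions and degenerate inputs

* Dosage orientation: minor allele counted, computed on the loaded/simulated
  sample set; frequency-0.5 ties go to the lexicographically smaller allele.
  Association P values are orientation-invariant; betas flip sign only.
* Raw P values are clipped below at 1e-300 (numerically perfect fits never
  report exactly 0, keeping the permutation null's entries in (0, 1]).
* A trait constant across breeds makes every SNP untestable: the scan emits
  all-absent P values and the permutation-null builder raises.
* Readers reject malformed input (half-missing genotype pairs, triallelic
  SNPs, column-count mismatches, duplicate breeds, inverted gene intervals)
  rather than repairing it; all writers emit files their paired readers
  accept bit-exactly (17-significant-digit floats, round-trip parsing).
* All randomness flows through `numpy` Generators from explicit seeds; the
  pipeline derives named per-stage substreams from one root seed, and a
  rerun from the same config is byte-identical.

## Known limitations

Binary PLINK (BED/BIM/FAM) and VCF ingestion are out of scope, as are
mixed-model/kinship corrections (the permutation scheme is the only
stratification control, as in the design this follows), haplotype tests,
within-breed mapping, and any network retrieval of gene lists or variant
annotations.
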