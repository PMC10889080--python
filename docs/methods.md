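# Methods

This note documents the models, estimators, defaults and numerical
choices behind `prspartition`, and what the synthetic-data validation
does and does not establish.

## Generative cohort model

**Genotypes.** Each LD block draws, per haplotype, a latent Gaussian
AR(1) series z₁…z_V (parameter ρ, default 0.8; optionally per-block
ρ ~ U(range) to emulate genome-wide LD heterogeneity); allele = 1 when
z < Φ⁻¹(MAF). Two haplotypes sum to a hard dosage in {0, 1, 2}, giving
Hardy–Weinberg-consistent genotypes whose pairwise correlation decays
geometrically in the latent metric (attenuated by the thresholding; the
tests compare against a brute-force simulation of the thresholded
bivariate model). Blocks are mutually independent and placed 3 Mb apart
on one chromosome, so the 1 Mb clump/merge windows and the 1.5 Mb proxy
window never span blocks. Per-variant MAF ~ U(0.05, 0.5). INFO is set
to 1.0 (imputation is not simulated; the QC filter still reads it) and
consequence labels are drawn from a fixed distribution so the proxy
tie-break is exercisable. Variant-level draws (MAF, alleles,
consequences) use a separate `variant_seed` stream so cohorts with
different sample seeds — replication panels — genotype the same
variants.

**Mechanism classes.** One causal variant per block, retention blocks
first: 10 *retention* (per-SD effects +0.15 on liver fat, −0.08 on
circulating TG), 13 *flux* (+0.10, +0.08), 3 *liver-only* (+0.10, 0);
all other variants are null. These counts deliberately mirror the
partition sizes the workflow is meant to recover (10 discordant /
13 concordant / 3 excluded) and the TG effects satisfy the ≥ 0.05 SD
magnitude under which the marginal TG sign is recoverable at n = 20,000.

**Phenotypes.** A single shared body-fat factor A drives the five
adiposity indices (loadings 0.90 VAT, 0.85 WFM, 0.80 BMI, 0.55 WHR,
−0.60 IWB — impedance falls with fat mass). Liver fat = genetic burden
+ 0.40·A + noise; TG = TG-genetics + 0.30·A + noise; inflammation =
0.70·liver fat + independent noise; all unit variance. Age, sex, ten
PCs and a two-level array batch are simulated independently of
genotype (no population structure), which keeps the null GWAS exactly
calibrated.

**Diseases.** Per disease a liability loads on the standardized genetic
liver-fat burden, observed TG, and A: liver disease (0.60, 0, 0.20,
prevalence 10%), liver cancer (0.70, 0, 0.10, 1.5%), cardiovascular
disease (0, 0.60, 0.20, 12%), diabetes (0.30, 0.30, 0.30, 10%).
Baseline (prevalent) status thresholds the standardized liability at
the normal quantile of the target prevalence; incident times are
exponential with log-hazard 0.3–0.5 per liability SD, administratively
censored at 15 years. Competing risks are not modelled.

## Estimators and procedures

**Penalized adiposity models.** Objective
(1/2n)‖y − Xb‖² + λ(α‖b‖₁ + (1−α)/2‖b‖²); unpenalized covariates (age,
sex, age², age·sex, age²·sex) are concentrated out exactly by
residualizing X and y on the covariate space — valid for any penalty
because the covariate block enters the loss quadratically. Ridge is
closed-form; otherwise Gram-matrix coordinate descent to 1e-8 on the
maximum coefficient change (cap 10⁵ sweeps). λ path: 50 (tests use
fewer) log-spaced values from λ_max down to 1e-4·λ_max; α grid
{0, 0.25, 0.5, 0.75, 1}. The λ-path floor bounds attainable training
error at ~(1e-4·λ_max)², which is why the noise-free selection test
asserts 1e-6 rather than machine zero. Nested CV: 80/20 split; 10-fold
outer CV compares the ridge / lasso / elastic-net families, each tuned
in a 10-fold inner CV by minimum MSE; the winner is re-tuned on the
full training set, evaluated on the held-out 20%, then refit on all
data. Fold assignment is seeded; selection is invariant to predictor
column order.

**Association scans.** Continuous traits are rank-inverse-normal
transformed with the Blom offset (r − 3/8)/(n + 1/4), ties by average
rank. The covariate block (intercept, centred-age polynomial and
interactions, 10 PCs, batch one-hot dropping the first level, plus at
most one adiposity index) is shared across variants, so the scan
residualizes trait and dosages on its QR basis once and reduces each
variant to a simple regression — algebraically identical to per-variant
OLS (checked to 1e-8 against statsmodels). Missing dosages are
mean-imputed per variant. Binary traits use statsmodels logistic
regression (Newton); perfect separation is flagged, not estimated.
Since simulated samples are unrelated, a plain covariate-adjusted GLM
is used in place of whole-genome (mixed-model) regression.

**Variant QC.** MAF > 0.01 on empirical frequencies, INFO > 0.8, exact
conditional Hardy–Weinberg test p > 1e-10 (heterozygote-count
enumeration with log-gamma arithmetic, summing outcomes no more
probable than observed). Exclusions are attributed to the first failing
filter in MAF → INFO → HWE order.

**Locus definition.** Clumping is greedy on ascending p (ties: larger
|β|, then smaller position), absorbing unassigned significant variants
within ±1000 kb with r² > 0.01; the output partitions the significant
set and matches brute-force enumeration on every random ≤15-variant
instance tried. Conditional-joint selection is forward stepwise over
clump leads: the candidate with the smallest conditional p in an exact
joint OLS (covariates + previously selected variants within 10 Mb)
enters while p < 5e-8 — with individual-level data the joint fit is
exact, so no external LD reference or summary approximation is needed.
Rank-deficient candidates are dropped and logged. The genome-wide
threshold is deliberately not corrected across adjustment runs.
Pleiotropy merging connects leads within 1 Mb at r² > 0.2 and takes
connected components as loci — the transitive closure is the minimal
consistent extension of the pairwise rule; the component lead is the
minimum-p member, and the pleiotropic flag requires ≥ 2 source
adjustments.

**LD score regression.** ℓ_j = Σ_k [r̂² − (1−r̂²)/(n−2)] over a ±1 Mb
window including j. Heritability: weighted regression (weights
1/max(ℓ,1)) of χ² = (β/se)² on n·ℓ/m with free intercept; χ² values are
retained up to 99,999 rather than capped at a conventional bound, so
large-effect loci stay in. SEs from a delete-one jackknife over 20
contiguous variant blocks; m < 200 is refused. Cross-trait: z₁z₂
regressed on √(n₁n₂)·ℓ/m; rg = cross-slope/√(h²₁h²₂), jackknifed as a
ratio; estimates in (1, 1.25] are tolerated and flagged. Known
small-genome caveats, measured in the tests: with only ~250 independent
blocks the per-replicate h² estimate is noisy (SE ≈ 0.11 at
n = m = 5000) and mildly attenuated at the high-ℓ end, and the rg ratio
inherits an upward Jensen-type bias when the denominator h² estimates
are noisy — hence the validation asserts on replicate means, and the
rg check uses strongly heritable (h² = 0.6) trait pairs.

**Partitioned scores.** Every locus lead is aligned to its
liver-fat-raising allele (weights therefore ≥ 0); the TG effect on that
allele classifies the locus: p ≥ 0.05 → excluded, negative →
discordant, positive → concordant. The 0.05 threshold is a documented
default exposed as `tg_alpha` (no stated value exists for "did not
associate"). Weights are the discovery liver-fat betas from the
adjustment that produced each lead; an equal-weights mode exists.
Scores are standardized in the scored sample; odds and hazard ratios
are per SD. Incremental R² is the difference of two nested OLS fits,
reported in percent. Cox models exclude prevalent cases before
fitting, use lifelines (Breslow ties) and report a scaled-residual
proportional-hazards p without enforcing it.

**Replication.** Per cohort the lead (or its best proxy: r² > 0.4
within ±1.5 Mb in the reference panel; max r², ties by a fixed
consequence-severity ordering missense > splice > UTR > synonymous >
intron > up/downstream > intergenic, then position) is tested with the
replication covariate set (age terms, sex, BMI; INT response). Proxy
effect signs are oriented by the dosage correlation with the target in
the reference panel. Pooling is inverse-variance fixed-effect; Q is
reported but never switches the model. Replication = pooled p < 0.05
and sign concordance with discovery, explicitly uncorrected for
multiple testing.

**Enrichment.** One-sided Fisher tests are upper-tail hypergeometric
probabilities at fixed margins (scipy exact routines; enumeration
oracles in the tests); the caller orients the table. The gene ranking
is the unweighted row sum over seven binary evidence sources consumed
as a precomputed matrix (their generators — positional/eQTL/chromatin
mapping, gene-based tests, colocalization, fine-mapping, V2G — are out
of scope); ties are all reported alphabetically.

**Pipeline.** Every stage reads and writes plain TSV with stable column
order; the report stage writes a sha256 manifest over all outputs.
All stage randomness derives from the run seed, so re-runs — full or
resumed from any retained intermediate — are byte-identical. Stage
defaults equal the workflow's published constants (QC 0.01/0.8/1e-10;
clump 5e-8/0.01/1000 kb; conditional window 10 Mb; merge 0.2/1 Mb;
proxy 0.4/1.5 Mb; tg_alpha 0.05), asserted literally by a test.

## Validation studies and their scope

Problem sizes were chosen so the full suite runs in a couple of
minutes: the demo partition study uses the default 20,000 × 1,200
cohort under two adjustments; heritability recovery uses a
5,000 × 5,000 panel with heterogeneous-LD blocks (the regression needs
LD-score spread for leverage) and 20 trait replicates; Cox recovery
uses n = 5,000 with ≈ 700 events; null calibration uses a 2,000-variant
permuted scan and 200 null-replication runs; the ridge-versus-lasso
comparison uses 20 replicates of a dense equal-effects design (five
predictors on one shared factor, the leading pair at r = 0.95,
n = 100) — the setting where L2's variance pooling across correlated
predictors is a structural advantage rather than a coin flip.

Passing these studies shows the *machinery* is correct and that the
mechanism-partition logic recovers a truth of exactly the hypothesized
form. It does not show that real biobank data satisfy the generative
assumptions: no relatedness or population structure, no imputation
error, hard dosages, block-diagonal LD, a single adiposity factor,
Gaussian liabilities, and exponential hazards. Quantities tied to real
cohorts (9.4 M variants, specific loci, 5.6%/7% PRS R², 6-of-26
replication) require controlled-access data and are outside what the
synthetic studies can reproduce; the validation targets the computable
worked examples and structure/parameter recovery instead.

## Known limitations

- Conditional-joint selection requires individual-level genotypes; a
  summary-statistics-only mode with an external LD panel is not
  implemented.
- Single-annotation LDSC only; no partitioned heritability or
  MAF/LD-dependent annotations. Intercept and slope semantics are
  preserved.
- The synthetic VCF stores hard genotypes with a DS field; imputation
  uncertainty is not represented.
- Proxy search scans candidate lists linearly — adequate at desk scale,
  not indexed for genome-wide panels.
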