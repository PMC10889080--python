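# prspartition

Partitioned polygenic risk scores for metabolic dysfunction-associated
steatotic liver disease (MASLD).

MASLD — excess liver triglyceride progressing to inflammation, cirrhosis
and liver cancer — epidemiologically travels with the cardiometabolic
syndrome, yet several of its strongest genetic risk factors *protect*
against cardiovascular disease. The resolution lies in mechanism: some
risk alleles impair hepatic VLDL export, so triglyceride is *retained*
in the hepatocyte and circulating triglycerides fall (liver-specific
disease, lower cardiovascular risk), while others increase substrate
uptake and synthesis, raising both liver fat and circulating lipids
(systemic cardiometabolic disease). `prspartition` implements the full
discovery-to-partition workflow that separates these two components and
exercises it end-to-end on a seeded synthetic biobank cohort whose
generative model encodes exactly those two mechanisms.

## What it implements

- **Synthetic biobank cohorts** (`synthcohort`): LD-blocked genotypes via
  Gaussian-copula AR(1) haplotype thresholding; correlated adiposity
  indices (VAT, WFM, BMI, WHR, IWB) from a shared body-fat factor;
  mechanism-labelled causal variants (*retention*: +liver fat, −TG;
  *flux*: +liver fat, +TG; *liver-only*: +liver fat, 0 TG);
  liability-threshold diseases and exponential incident event times
  with administrative censoring. VCF (per-genotype DS dosage) and TSV
  round-trip I/O.
- **Adiposity model selection** (`adiposity`): ridge / lasso /
  elastic-net with unpenalized demographic covariates, selected by
  nested cross-validation (80/20 split, 10-fold outer and inner CV),
  and the standardized-coefficient ranking of the indices.
- **GWAS engine** (`gwas`): variant QC (MAF > 0.01, INFO > 0.8, exact
  Hardy–Weinberg p > 1e-10), rank-based inverse-normal transform (Blom
  offset), per-variant covariate-adjusted OLS for continuous traits
  under each adiposity adjustment, logistic regression for binary
  traits.
- **Locus definition** (`loci`): greedy LD clumping (p < 5e-8,
  r² > 0.01, ±1 Mb), forward stepwise conditional-joint selection
  (exact joint regression, 10 Mb window), and pleiotropy merging of
  leads across adjustments (r² > 0.2 within 1 Mb, connected
  components).
- **LD score regression** (`ldsc`): single-annotation LD scores with
  small-sample bias adjustment, SNP heritability (slope) and
  confounding intercept with 20-block jackknife SEs, cross-trait
  genetic correlation, BH-FDR.
- **Partitioned PRS** (`prs`): alignment of every locus to its
  liver-fat-raising allele, classification as *discordant* (negative TG
  effect), *concordant* (positive) or *excluded* (TG p ≥ 0.05), scoring,
  incremental variance explained, logistic odds ratios and Cox hazard
  ratios per SD of score (prevalent cases excluded from the
  prospective models; Schoenfeld-type diagnostic reported).
- **Replication meta-analysis** (`meta`): per-cohort association with
  the replication covariate set, LD-proxy substitution (r² > 0.4 within
  1.5 Mb, ties by consequence severity), inverse-variance fixed-effect
  pooling with Cochran Q, and the replicated flag (pooled p < 0.05 and
  sign-consistent with discovery).
- **Enrichment** (`enrich`): one-sided Fisher exact tests (hypergeometric
  upper tail), gene-set overlap against a universe, and the unweighted
  seven-source gene-evidence ranking.
- **Pipeline** (`pipeline` / CLI `prspartition`): stage-wise TSV outputs,
  sha256 run manifest, byte-identical re-runs, resumable from any
  retained intermediate.

## Worked example

Run the demo pipeline (4,000 samples, 300 variants in 30 LD blocks,
10 retention + 13 flux + 3 liver-only causal variants) from Python:

```python
from prspartition.pipeline import PipelineConfig, run_pipeline
from prspartition.synthcohort import SimConfig

cfg = PipelineConfig(
    sim=SimConfig(n_samples=4000, n_blocks=30, variants_per_block=10, seed=5),
    adjustments=("none", "BMI"), n_replication_cohorts=3,
    replication_n=700, seed=5,
)
run_pipeline(cfg, "demo_run")
print(open("demo_run/summary.txt").read())
```

which prints:

```
partitioned-PRS pipeline summary
seed: 5
variants kept after QC: 300 (excluded {'HWE': 0, 'INFO': 0, 'MAF': 0})
merged independent loci: 26 (pleiotropic: 24)
partition sizes: discordant=11, concordant=13, excluded=2
incremental R2 (%): full=37.18, discordant=22.38, concordant=12.22
replicated loci: 26/26 (nominal p<0.05, sign-consistent; not adjusted for multiple testing)
```

All 26 causal loci are found and merged across the two adjustment runs;
the concordance partition recovers the hidden mechanism classes almost
exactly (11/13/2 against a 10/13/3 truth at this sample size). The
disease table (`demo_run/prs_assoc.tsv`) shows the signature pattern —
the discordant score raises liver-disease risk (OR 1.93 per SD,
95% CI 1.77–2.12) while *protecting* from cardiovascular disease
(OR 0.82, 0.75–0.89), whereas the concordant score raises
cardiovascular risk (OR 1.21, 1.12–1.31); both raise diabetes risk.

The same objects are available as library calls (`gwas.run_gwas`,
`loci.clump`, `prs.partition_by_concordance`, `meta.replicate`, …) and
as CLI subcommands (`prspartition simulate/run/gwas/clump/ldsc/
select-adiposity/fisher/rank-genes`). For example, the published
liver-cancer enrichment contrast:

```bash
$ prspartition fisher --table 4,5,1,16
0.0344786
```

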