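"""Seeded generator of biobank-like cohorts for liver-fat genetics analyses.

The generator emulates the data layout of an imaging-substudy biobank:
LD-blocked imputed genotypes, a panel of correlated adiposity indices
(VAT, WFM, BMI, WHR, IWB driven by a shared body-fat factor), two MRI-style
liver traits (liver fat and a downstream inflammation proxy), circulating
triglycerides, and liability-threshold diseases with exponential incident
event times under administrative censoring.

Causal variants carry mechanism labels encoding two routes to a fatty
liver: *retention* variants raise liver fat while lowering circulating
triglycerides (impaired VLDL export keeps lipid in the hepatocyte), *flux*
variants raise both (increased substrate uptake/synthesis feeds both
pools), and *liver_only* variants raise liver fat without any triglyceride
effect. Everything else is a null variant. The hidden mechanism table is
the ground truth against which the discordant/concordant partition of the
downstream PRS modules is scored.

Genotypes use a Gaussian-copula AR(1) haplotype model: within each block a
latent AR(1) Gaussian is thresholded at the allele-frequency quantile per
haplotype and the two haplotypes are summed, giving Hardy-Weinberg-
consistent hard dosages with geometrically decaying LD. Blocks are placed
>1 Mb apart and are mutually independent.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "OutcomeModel",
    "Cohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_phenotypes",
    "standardize_genotypes",
    "DEFAULT_ADIPOSITY_LOADINGS",
    "CONSEQUENCES",
]

CONSEQUENCES = (
    "missense_variant",
    "splice_region_variant",
    "5_prime_UTR_variant",
    "synonymous_variant",
    "intron_variant",
    "upstream_gene_variant",
    "intergenic_variant",
)
DEFAULT_CONSEQUENCE_PROBS = (0.05, 0.03, 0.05, 0.07, 0.45, 0.10, 0.25)

# Loadings of each adiposity index on the single shared body-fat factor;
# impedance (IWB) decreases with fat mass, hence the negative loading.
DEFAULT_ADIPOSITY_LOADINGS = {
    "VAT": 0.90,
    "WFM": 0.85,
    "BMI": 0.80,
    "WHR": 0.55,
    "IWB": -0.60,
}

ADIPOSITY_TRAITS = ("VAT", "WFM", "BMI", "WHR", "IWB")
CONTINUOUS_TRAITS = ("liver_fat", "liver_inflammation", "tg") + ADIPOSITY_TRAITS
CORE_COVARIATES = ("age", "sex", "batch") + tuple(f"PC{i}" for i in range(1, 11))

MECHANISM_CLASSES = ("retention", "flux", "liver_only", "null")


@dataclass(frozen=True)
class OutcomeModel:
    """Liability loadings and event-time parameters for one binary disease.

    The liability is ``w_liver_genetic * Z(genetic liver-fat burden) +
    w_tg * Z(observed TG) + w_adiposity * (shared adiposity factor) +
    noise``, standardized, and thresholded at the normal quantile of
    ``prevalence`` for baseline (prevalent) status. Incident event times
    are exponential with log-hazard ``log_hr_per_sd`` per SD of the same
    liability, right-censored administratively at ``horizon`` years.
    """

    prevalence: float
    w_liver_genetic: float = 0.0
    w_tg: float = 0.0
    w_adiposity: float = 0.0
    log_hr_per_sd: float = 0.3
    baseline_hazard: float = 0.005
    horizon: float = 15.0


def default_outcome_models() -> dict[str, OutcomeModel]:
    """Generic stand-in diseases wired to the mechanism model.

    Liver disease and liver cancer are driven by the genetic liver-fat
    burden, cardiovascular disease by circulating triglycerides, and
    diabetes by both plus adiposity.
    """
    return {
        "liver_disease": OutcomeModel(0.10, w_liver_genetic=0.60, w_adiposity=0.20),
        "hcc": OutcomeModel(0.015, w_liver_genetic=0.70, w_adiposity=0.10,
                            log_hr_per_sd=0.5, baseline_hazard=0.0008),
        "cvd": OutcomeModel(0.12, w_tg=0.60, w_adiposity=0.20,
                            baseline_hazard=0.006),
        "diabetes": OutcomeModel(0.10, w_liver_genetic=0.30, w_tg=0.30,
                                 w_adiposity=0.30),
    }


@dataclass(frozen=True)
class SimConfig:
    """Generative model of the study cohort.

    Effect sizes are per-SD of dosage (standardized genotypes). Class
    counts allocate one causal variant per LD block, retention blocks
    first; the remaining variants are null.
    """

    n_samples: int = 20000
    n_blocks: int = 40
    variants_per_block: int = 30
    ar1_rho: float = 0.8
    # optional per-block LD heterogeneity: when set, each block draws its
    # own AR(1) parameter uniformly from this range (variant stream), so
    # LD scores vary across the genome as they do in real data
    ar1_rho_range: tuple[float, float] | None = None
    maf_range: tuple[float, float] = (0.05, 0.50)
    n_retention: int = 10
    n_flux: int = 13
    n_liver_only: int = 3
    n_null: int | None = None
    beta_liver: dict[str, float] = field(
        default_factory=lambda: {"retention": 0.15, "flux": 0.10, "liver_only": 0.10}
    )
    beta_tg: dict[str, float] = field(
        default_factory=lambda: {"retention": -0.08, "flux": 0.08, "liver_only": 0.0}
    )
    adiposity_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADIPOSITY_LOADINGS)
    )
    liver_adiposity: float = 0.40   # loading of liver fat on the shared factor
    tg_adiposity: float = 0.30      # loading of TG on the shared factor
    inflammation_scale: float = 0.70
    outcome_models: dict[str, OutcomeModel] = field(default_factory=default_outcome_models)
    consequence_probs: tuple[float, ...] = DEFAULT_CONSEQUENCE_PROBS
    seed: int = 0
    # variant-level draws (MAF, alleles, consequence labels) use their own
    # stream so cohorts simulated with different seeds — e.g. replication
    # panels — genotype the *same* variant set as the discovery cohort
    variant_seed: int = 13

    def __post_init__(self):
        for name in ("n_samples", "n_blocks", "variants_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError(f"ar1_rho must lie in [0, 1), got {self.ar1_rho}")
        if self.ar1_rho_range is not None:
            lo, hi = self.ar1_rho_range
            if not (0.0 <= lo <= hi < 1.0):
                raise ValueError("ar1_rho_range must lie within [0, 1)")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0.01 < lo <= hi <= 0.5, got {self.maf_range}")
        m = self.n_blocks * self.variants_per_block
        n_causal = self.n_retention + self.n_flux + self.n_liver_only
        if min(self.n_retention, self.n_flux, self.n_liver_only) < 0:
            raise ValueError("causal class counts must be non-negative")
        if n_causal > self.n_blocks:
            raise ValueError(
                f"one causal variant per block: {n_causal} causal classes > {self.n_blocks} blocks"
            )
        if self.n_null is not None and n_causal + self.n_null > m:
            raise ValueError("class counts sum exceeds the total variant count")
        for d in (self.beta_liver, self.beta_tg):
            for v in d.values():
                if not np.isfinite(v):
                    raise ValueError("every effect size must be finite")
        if self.n_retention and self.beta_tg.get("retention", 0.0) >= 0:
            raise ValueError("retention TG effect must be strictly negative")
        if self.n_flux and self.beta_tg.get("flux", 0.0) <= 0:
            raise ValueError("flux TG effect must be strictly positive")
        if abs(sum(self.consequence_probs) - 1.0) > 1e-9:
            raise ValueError("consequence_probs must sum to 1")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.variants_per_block

    def causal_table(self) -> pd.DataFrame:
        """Mechanism class and true per-SD betas by variant index."""
        m = self.n_variants
        labels = np.array(["null"] * m, dtype=object)
        bl = np.zeros(m)
        bt = np.zeros(m)
        centre = self.variants_per_block // 2
        block = 0
        for cls, count in (
            ("retention", self.n_retention),
            ("flux", self.n_flux),
            ("liver_only", self.n_liver_only),
        ):
            for _ in range(count):
                j = block * self.variants_per_block + centre
                labels[j] = cls
                bl[j] = self.beta_liver[cls]
                bt[j] = self.beta_tg[cls]
                block += 1
        return pd.DataFrame({"class": labels, "beta_liver": bl, "beta_tg": bt})


@dataclass
class Cohort:
    """Genotype dosages with variant metadata, phenotypes, and (for
    simulated cohorts) the hidden mechanism truth."""

    genotypes: np.ndarray            # n_samples x n_variants, dosages in [0, 2]
    variants: pd.DataFrame           # chrom, pos, id, ea, oa, maf, info, consequence
    phenotypes: pd.DataFrame         # indexed by sample id
    mechanism: pd.DataFrame | None = None

    def __post_init__(self):
        n, m = self.genotypes.shape
        if len(self.variants) != m:
            raise ValueError("variant metadata length does not match genotype columns")
        if len(self.phenotypes) != n:
            raise ValueError("phenotype rows do not match genotype rows")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants["id"])}


def standardize_genotypes(G: np.ndarray) -> np.ndarray:
    """Column-standardize dosages (zero mean, unit variance); constant
    columns are left at zero."""
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (G - mu) / sd


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw LD-blocked hard dosages and the variant metadata table.

    Within a block each haplotype is a latent AR(1) Gaussian thresholded
    at the per-variant MAF quantile; the two haplotypes are summed. Blocks
    are independent and placed 3 Mb apart on one chromosome.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    meta_rng = np.random.default_rng([config.variant_seed, 100])
    n, B, V = config.n_samples, config.n_blocks, config.variants_per_block
    mafs = meta_rng.uniform(*config.maf_range, size=B * V)
    if config.ar1_rho_range is not None:
        rhos = meta_rng.uniform(*config.ar1_rho_range, size=B)
    else:
        rhos = np.full(B, config.ar1_rho)
    thresholds = norm.ppf(mafs).reshape(B, V)
    G = np.empty((n, B * V), dtype=np.float64)
    for b in range(B):
        rho = rhos[b]
        innov = np.sqrt(1.0 - rho**2)
        dose = np.zeros((n, V))
        for _hap in range(2):
            z = np.empty((n, V))
            z[:, 0] = rng.standard_normal(n)
            for k in range(1, V):
                z[:, k] = rho * z[:, k - 1] + innov * rng.standard_normal(n)
            dose += z < thresholds[b]
        G[:, b * V:(b + 1) * V] = dose

    pos = np.concatenate(
        [1_000_000 + b * 3_000_000 + np.arange(V) * 1_000 for b in range(B)]
    )
    allele_pairs = [("A", "G"), ("C", "T"), ("T", "A"), ("G", "C")]
    pick = meta_rng.integers(0, len(allele_pairs), size=B * V)
    consequence = meta_rng.choice(CONSEQUENCES, size=B * V, p=config.consequence_probs)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos.astype(np.int64),
            "id": [f"rs{100000 + j}" for j in range(B * V)],
            "ea": [allele_pairs[k][0] for k in pick],
            "oa": [allele_pairs[k][1] for k in pick],
            "maf": mafs,
            "info": 1.0,
            "consequence": consequence,
        }
    )
    return G, variants


def simulate_phenotypes(
    G: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Generate phenotypes, covariates and outcomes plus the mechanism table."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    n, m = G.shape
    if m != config.n_variants:
        raise ValueError("genotype matrix does not match config dimensions")
    mech = config.causal_table()
    Gs = standardize_genotypes(G)
    g_liver = Gs @ mech["beta_liver"].to_numpy()
    g_tg = Gs @ mech["beta_tg"].to_numpy()

    # Shared body-fat factor drives all adiposity indices and part of the
    # liver-fat and TG variance; traits are scaled to unit total variance.
    A = rng.standard_normal(n)
    pheno = {}
    for name, load in config.adiposity_loadings.items():
        spec = np.sqrt(max(1.0 - load**2, 0.0))
        pheno[name] = load * A + spec * rng.standard_normal(n)

    var_g_liver = float(np.sum(mech["beta_liver"] ** 2))
    var_g_tg = float(np.sum(mech["beta_tg"] ** 2))
    res_liver = 1.0 - var_g_liver - config.liver_adiposity**2
    res_tg = 1.0 - var_g_tg - config.tg_adiposity**2
    if res_liver <= 0 or res_tg <= 0:
        raise ValueError("genetic plus adiposity variance exceeds 1; reduce effect sizes")
    liver_fat = g_liver + config.liver_adiposity * A + np.sqrt(res_liver) * rng.standard_normal(n)
    tg = g_tg + config.tg_adiposity * A + np.sqrt(res_tg) * rng.standard_normal(n)
    s = config.inflammation_scale
    liver_inflammation = s * liver_fat + np.sqrt(max(1 - s**2, 0.0)) * rng.standard_normal(n)

    pheno["liver_fat"] = liver_fat
    pheno["liver_inflammation"] = liver_inflammation
    pheno["tg"] = tg
    pheno["age"] = rng.uniform(40.0, 70.0, size=n).round(1)
    pheno["sex"] = rng.integers(0, 2, size=n).astype(np.int64)
    for i in range(1, 11):
        pheno[f"PC{i}"] = rng.standard_normal(n)
    pheno["batch"] = rng.integers(0, 2, size=n).astype(np.int64)

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    z_gl, z_tg = _z(g_liver) if var_g_liver > 0 else np.zeros(n), _z(tg)
    for disease, om in config.outcome_models.items():
        loading_var = om.w_liver_genetic**2 + om.w_tg**2 + om.w_adiposity**2
        noise = np.sqrt(max(1.0 - loading_var, 0.05))
        liability = (
            om.w_liver_genetic * z_gl
            + om.w_tg * z_tg
            + om.w_adiposity * A
            + noise * rng.standard_normal(n)
        )
        liability = _z(liability)
        prevalent = liability > norm.isf(om.prevalence)
        hazard = om.baseline_hazard * np.exp(om.log_hr_per_sd * liability)
        t_event = rng.exponential(1.0 / hazard)
        event = t_event < om.horizon
        time = np.minimum(t_event, om.horizon)
        case = prevalent | event
        frac = case.mean()
        if frac <= 0.0 or frac >= 1.0:
            raise ValueError(
                f"outcome '{disease}' has degenerate prevalence {frac:.4f} after thresholding"
            )
        pheno[disease] = case.astype(np.int64)
        pheno[f"{disease}_prevalent"] = prevalent.astype(np.int64)
        pheno[f"{disease}_event"] = event.astype(np.int64)
        pheno[f"{disease}_time"] = time

    phenotypes = pd.DataFrame(pheno, index=[f"S{i:06d}" for i in range(n)])
    phenotypes.index.name = "sample_id"
    return phenotypes, mech


def simulate_cohort(config: SimConfig) -> Cohort:
    """Full seeded cohort draw: genotypes, phenotypes, mechanism truth."""
    G, variants = simulate_genotypes(config)
    phenotypes, mech = simulate_phenotypes(G, config)
    mech = mech.copy()
    mech.insert(0, "id", variants["id"].to_numpy())
    return Cohort(G, variants, phenotypes, mech)


# ---------------------------------------------------------------------------
# Serialization: VCF (DS dosage) or dosage TSV + phenotype/mechanism TSVs
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=MAF,Number=1,Type=Float,Description="Configured minor allele frequency">
##INFO=<ID=IS,Number=1,Type=Float,Description="Imputation INFO score">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence label">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the alternate (effect) allele">
##contig=<ID=1>
"""

_DOSAGE_DECIMALS = 3


def write_cohort(cohort: Cohort, outdir: str, genotype_format: str = "vcf") -> dict[str, str]:
    """Write the cohort as plain-text files; returns the path map.

    The VCF stores the effect allele as ALT with a per-genotype DS field
    (3 decimals) and hard GT calls from rounded dosage; positions are
    1-based. ``genotype_format='tsv'`` writes a samples x variants dosage
    matrix instead.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "variants": os.path.join(outdir, "variants.tsv"),
    }
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t")
    cohort.variants.to_csv(paths["variants"], sep="\t", index=False)
    if cohort.mechanism is not None:
        paths["mechanism"] = os.path.join(outdir, "mechanism.tsv")
        cohort.mechanism.to_csv(paths["mechanism"], sep="\t", index=False)

    samples = list(cohort.phenotypes.index)
    if genotype_format == "vcf":
        paths["genotypes"] = os.path.join(outdir, "genotypes.vcf")
        with open(paths["genotypes"], "w") as fh:
            fh.write(_VCF_HEADER)
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            G = cohort.genotypes
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
            for j, v in cohort.variants.iterrows():
                ds = G[:, j]
                hard = np.clip(np.rint(ds), 0, 2).astype(int)
                cells = [
                    f"{gt_codes[h]}:{d:.{_DOSAGE_DECIMALS}f}" for h, d in zip(hard, ds)
                ]
                fh.write(
                    f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['oa']}\t{v['ea']}\t.\tPASS\t"
                    f"MAF={v['maf']:.6g};IS={v['info']:.4g};CSQ={v['consequence']}\tGT:DS\t"
                    + "\t".join(cells)
                    + "\n"
                )
    elif genotype_format == "tsv":
        paths["genotypes"] = os.path.join(outdir, "genotypes.tsv")
        df = pd.DataFrame(
            np.round(cohort.genotypes, _DOSAGE_DECIMALS),
            index=samples,
            columns=cohort.variants["id"],
        )
        df.index.name = "sample_id"
        df.to_csv(paths["genotypes"], sep="\t")
    else:
        raise ValueError(f"unknown genotype_format {genotype_format!r}")
    return paths


def validate_phenotypes(df: pd.DataFrame, required=("liver_fat", "tg") + CORE_COVARIATES):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table is missing required column(s): {', '.join(missing)}")


def _read_vcf(path: str):
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=np.float64).reshape(-1)
        else:
            # fall back to hard genotypes (count of ALT alleles)
            dose = np.asarray(var.gt_types, dtype=np.float64)
            dose[dose == 2] = np.nan   # UNKNOWN
            dose[dose == 3] = 2.0      # HOM_ALT
        cols.append(dose)
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": int(var.POS),
                "id": var.ID,
                "ea": var.ALT[0],
                "oa": var.REF,
                "maf": float(var.INFO.get("MAF", np.nan)),
                "info": float(var.INFO.get("IS", np.nan)),
                "consequence": var.INFO.get("CSQ", "unknown"),
            }
        )
    G = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return G, pd.DataFrame(rows), samples


def read_cohort(indir: str, require_mechanism: bool = False) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (VCF or dosage TSV)."""
    pheno_path = os.path.join(indir, "phenotypes.tsv")
    try:
        phenotypes = pd.read_csv(pheno_path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"failed to parse phenotype table {pheno_path}: {exc}") from exc
    validate_phenotypes(phenotypes)

    vcf_path = os.path.join(indir, "genotypes.vcf")
    tsv_path = os.path.join(indir, "genotypes.tsv")
    if os.path.exists(vcf_path):
        G, variants, samples = _read_vcf(vcf_path)
        if list(phenotypes.index) != samples:
            raise ValueError("sample order differs between VCF and phenotype table")
    elif os.path.exists(tsv_path):
        df = pd.read_csv(tsv_path, sep="\t", index_col=0)
        if list(df.index) != list(phenotypes.index):
            raise ValueError("sample order differs between dosage matrix and phenotype table")
        G = df.to_numpy(dtype=np.float64)
        variants = pd.read_csv(os.path.join(indir, "variants.tsv"), sep="\t",
                               dtype={"chrom": str})
    else:
        raise FileNotFoundError(f"no genotypes.vcf or genotypes.tsv under {indir}")

    vpath = os.path.join(indir, "variants.tsv")
    if os.path.exists(vpath):
        meta = pd.read_csv(vpath, sep="\t", dtype={"chrom": str})
        if len(meta) != G.shape[1]:
            raise ValueError("variants.tsv length does not match the genotype matrix")
        variants = meta

    mech = None
    mpath = os.path.join(indir, "mechanism.tsv")
    if os.path.exists(mpath):
        # keep_default_na: the mechanism class 'null' is a real label
        mech = pd.read_csv(mpath, sep="\t", keep_default_na=False)
        for col in ("beta_liver", "beta_tg"):
            mech[col] = mech[col].astype(float)
    elif require_mechanism:
        raise FileNotFoundError(f"mechanism.tsv not found under {indir}")
    return Cohort(G, variants, phenotypes, mech)
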