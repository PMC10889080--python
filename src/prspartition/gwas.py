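"""Variant QC and covariate-adjusted per-variant association engine.

Continuous traits are rank-based inverse-normal transformed (Blom offset)
and tested by OLS of the transformed trait on dosage plus covariates; each
adiposity adjustment adds exactly one adiposity index to the covariate
set {age, sex, age^2, age x sex, age^2 x sex, PC1-10, array batch}.
Binary traits use logistic regression with the same covariates. Because
the shared covariate block is identical across variants, the linear scan
residualizes trait and dosages on the covariates once (Frisch-Waugh-
Lovell) and reduces each variant to a simple regression — algebraically
identical to the full per-variant OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .synthcohort import Cohort

__all__ = [
    "ADJUSTMENTS",
    "SUMSTAT_COLUMNS",
    "AssocResult",
    "PerfectSeparation",
    "qc_filter",
    "hwe_exact_test",
    "inverse_normal_transform",
    "covariate_matrix",
    "run_gwas",
    "logistic_assoc",
    "genomic_lambda",
    "write_sumstats",
    "read_sumstats",
]

ADJUSTMENTS = ("none", "BMI", "WFM", "VAT", "WHR")

SUMSTAT_COLUMNS = ["CHR", "POS", "ID", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "TRAIT", "ADJ"]


@dataclass
class AssocResult:
    variant_id: str
    trait: str
    adjustment: str
    effect_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError("effect-allele frequency must lie in (0, 1)")


class PerfectSeparation(RuntimeError):
    """Raised when a logistic fit is perfectly separated (no finite MLE)."""


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts whose conditional probability does not
    exceed that of the observed count.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = int(sum(counts))
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    na = 2 * n_AA + n_Aa          # count of the A allele
    na = min(na, 2 * n - na)      # work with the rarer allele
    het = np.arange(na % 2, na + 1, 2)
    rare_hom = (na - het) // 2
    common_hom = n - het - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(rare_hom + 1)
        - gammaln(het + 1)
        - gammaln(common_hom + 1)
        + het * np.log(2.0)
        + gammaln(na + 1)
        + gammaln(2 * n - na + 1)
        - gammaln(2 * n + 1)
    )
    logp -= logsumexp(logp)
    # folding to the rarer allele leaves the heterozygote count unchanged
    obs = np.flatnonzero(het == n_Aa)
    if obs.size == 0:
        raise ValueError("inconsistent genotype counts")
    p_obs = logp[obs[0]]
    keep = logp <= p_obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def qc_filter(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    maf_min: float = 0.01,
    info_min: float = 0.8,
    hwe_min: float = 1e-10,
):
    """Standard imputation-era variant QC.

    Keeps variants with empirical MAF > ``maf_min``, INFO > ``info_min``
    and exact Hardy-Weinberg p > ``hwe_min``. Returns a boolean keep mask
    and per-filter exclusion counts (a variant is attributed to the first
    filter it fails, in MAF -> INFO -> HWE order).
    """
    m = genotypes.shape[1]
    freq = np.nanmean(genotypes, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    info = variants["info"].to_numpy(dtype=float)
    keep = np.ones(m, dtype=bool)
    reasons = {"MAF": 0, "INFO": 0, "HWE": 0}
    hard = np.clip(np.rint(genotypes), 0, 2)
    for j in range(m):
        if not maf[j] > maf_min:
            keep[j] = False
            reasons["MAF"] += 1
            continue
        if not info[j] > info_min:
            keep[j] = False
            reasons["INFO"] += 1
            continue
        col = hard[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        if hwe_exact_test(n_aa, n_ab, n_bb) <= hwe_min:
            keep[j] = False
            reasons["HWE"] += 1
    return keep, reasons


# ---------------------------------------------------------------------------
# Inverse-normal transform
# ---------------------------------------------------------------------------

def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset
    (r - 3/8)/(n + 1/4); ties receive the average rank."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector with at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("cannot transform a constant vector")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))


# ---------------------------------------------------------------------------
# Covariates and the linear scan
# ---------------------------------------------------------------------------

def covariate_matrix(
    pheno: pd.DataFrame,
    adjustment: str = "none",
    covariate_set: str = "discovery",
) -> np.ndarray:
    """Design matrix of the shared (non-genetic) covariate block.

    ``discovery``: intercept, age, sex, age^2, age x sex, age^2 x sex,
    PC1-10 and batch (one-hot, first level dropped), plus one adiposity
    index when ``adjustment != 'none'``. ``replication`` uses the leaner
    replication-cohort set: intercept, age terms and BMI.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}; expected one of {ADJUSTMENTS}")
    age = pheno["age"].to_numpy(dtype=float)
    sex = pheno["sex"].to_numpy(dtype=float)
    agec = age - age.mean()  # centred to keep the polynomial terms well conditioned
    cols = [np.ones(len(pheno)), agec, sex, agec**2, agec * sex, agec**2 * sex]
    names = ["const", "age", "sex", "age2", "age_sex", "age2_sex"]
    if covariate_set == "discovery":
        for i in range(1, 11):
            cols.append(pheno[f"PC{i}"].to_numpy(dtype=float))
            names.append(f"PC{i}")
        batch = pd.get_dummies(pheno["batch"], drop_first=True)
        for c in batch.columns:
            cols.append(batch[c].to_numpy(dtype=float))
            names.append(f"batch_{c}")
        if adjustment != "none":
            cols.append(pheno[adjustment].to_numpy(dtype=float))
            names.append(adjustment)
    elif covariate_set == "replication":
        cols.append(pheno["BMI"].to_numpy(dtype=float))
        names.append("BMI")
    else:
        raise ValueError(f"unknown covariate_set {covariate_set!r}")
    C = np.column_stack(cols)
    # collinearity check with the offending pair named
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        corr = np.corrcoef(C[:, 1:], rowvar=False)
        iu = np.triu_indices_from(corr, k=1)
        worst = np.argmax(np.abs(corr[iu]))
        a, b = iu[0][worst] + 1, iu[1][worst] + 1
        raise ValueError(f"collinear covariates: {names[a]} and {names[b]}")
    return C


def _mean_impute(G: np.ndarray) -> np.ndarray:
    if not np.isnan(G).any():
        return G
    G = G.copy()
    mu = np.nanmean(G, axis=0)
    idx = np.where(np.isnan(G))
    G[idx] = mu[idx[1]]
    return G


def run_gwas(
    cohort: Cohort,
    trait: str,
    adjustment: str = "none",
    transform: bool = True,
    variant_mask: np.ndarray | None = None,
    covariate_set: str = "discovery",
) -> pd.DataFrame:
    """Per-variant OLS association scan of a continuous trait.

    Returns summary statistics in the standard TSV schema (one row per
    QC-passed variant). Missing dosages are mean-imputed per variant.
    """
    y = cohort.phenotypes[trait].to_numpy(dtype=float)
    if transform:
        y = inverse_normal_transform(y)
    C = covariate_matrix(cohort.phenotypes, adjustment, covariate_set)
    n, k = C.shape
    G = cohort.genotypes
    variants = cohort.variants
    if variant_mask is not None:
        G = G[:, variant_mask]
        variants = variants.loc[np.asarray(variant_mask)].reset_index(drop=True)
    G = _mean_impute(G)

    Q, _ = np.linalg.qr(C)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    ok = gg > 1e-12
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    beta[ok] = gy[ok] / gg[ok]
    dof = n - k - 1
    rss = (yr @ yr) - beta * gy
    sigma2 = np.maximum(rss, 0.0) / dof
    se[ok] = np.sqrt(sigma2[ok] / gg[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "CHR": variants["chrom"].to_numpy(),
            "POS": variants["pos"].to_numpy(),
            "ID": variants["id"].to_numpy(),
            "EA": variants["ea"].to_numpy(),
            "OA": variants["oa"].to_numpy(),
            "EAF": G.mean(axis=0) / 2.0,
            "BETA": beta,
            "SE": se,
            "P": p,
            "N": n,
            "TRAIT": trait,
            "ADJ": adjustment,
        }
    )
    return out[ok].reset_index(drop=True)


def genomic_lambda(p_values) -> float:
    """Genomic-control lambda: median chi-square over its null median."""
    chi2 = stats.chi2.isf(np.asarray(p_values, dtype=float), df=1)
    return float(np.median(chi2) / 0.4549364231195724)


# ---------------------------------------------------------------------------
# Logistic association
# ---------------------------------------------------------------------------

def logistic_assoc(
    predictor,
    outcome,
    covariates: np.ndarray | None = None,
    name: str = "x",
) -> dict:
    """Wald test from a logistic regression of a binary outcome on one
    predictor plus covariates; raises :class:`PerfectSeparation` when the
    MLE does not exist."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
        raise ValueError("outcome must be binary with both classes present")
    if covariates is None:
        X = np.column_stack([np.ones_like(x), x])
    else:
        X = np.column_stack([covariates, x])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton", tol=1e-10)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise PerfectSeparation(f"perfect separation fitting {name}") from exc
    beta = fit.params[-1]
    se = fit.bse[-1]
    if not np.isfinite(se) or abs(beta) > 50:
        raise PerfectSeparation(f"perfect separation fitting {name}")
    return {
        "name": name,
        "beta": float(beta),
        "se": float(se),
        "or": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
        "p": float(fit.pvalues[-1]),
        "n": int(len(y)),
        "n_events": int(y.sum()),
    }


# ---------------------------------------------------------------------------
# Summary-statistics I/O
# ---------------------------------------------------------------------------

def write_sumstats(ss: pd.DataFrame, path: str) -> None:
    ss.loc[:, SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sumstats(path: str) -> pd.DataFrame:
    ss = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in ss.columns]
    if missing:
        raise ValueError(f"summary statistics {path} missing column(s): {', '.join(missing)}")
    return ss
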