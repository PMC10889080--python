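"""Single-annotation LD score regression.

Per-variant LD scores are window sums of bias-adjusted squared
correlations; SNP heritability comes from a weighted regression of the
GWAS chi-square on n*l/m with a free intercept (slope = h2, intercept =
confounding), and cross-trait genetic correlation from the analogous
regression of the z-score product. Standard errors use a delete-one
jackknife over 20 contiguous variant blocks.

Under a polygenic model with per-variant heritability h2/m,
E[chi2_j] = 1 + n * h2 * l_j / m, which is the regression exploited here;
the intercept absorbs confounding inflation (and, for the cross-trait
version, sample overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdscFit",
    "compute_ld_scores",
    "estimate_h2",
    "genetic_correlation",
    "bh_fdr",
    "CHI2_MAX",
]

# Large-effect associations are deliberately retained: the chi-square cap
# is set to an arbitrarily large value rather than the conventional 80.
CHI2_MAX = 99999.0

N_JACKKNIFE_BLOCKS = 20
MIN_VARIANTS = 200


@dataclass
class LdscFit:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    rg: float | None = None
    rg_se: float | None = None
    chi2_max: float = CHI2_MAX
    flagged: bool = False

    def __post_init__(self):
        if self.rg is not None and abs(self.rg) > 1.25:
            self.flagged = True


def compute_ld_scores(
    genotypes: np.ndarray,
    positions: np.ndarray,
    window_kb: float = 1000.0,
    chrom: np.ndarray | None = None,
    adjusted: bool = True,
) -> np.ndarray:
    """Bias-adjusted LD scores l_j = sum_k [r2_jk - (1 - r2_jk)/(n - 2)]
    over variants k within the window (including j itself).

    ``adjusted=False`` returns the raw sum of squared correlations,
    which is exactly monotone in the window size (the adjusted score is
    monotone only in expectation, since null neighbours contribute
    mean-zero terms)."""
    if window_kb <= 0:
        raise ValueError("window must be positive")
    n, m = genotypes.shape
    pos = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos, kind="mergesort")
    if not np.array_equal(order, np.arange(m)) and chrom is None:
        raise ValueError("positions must be sorted (or supply chromosome labels)")
    if chrom is None:
        chrom = np.zeros(m, dtype=np.int64)
    chrom = np.asarray(chrom)
    mu = genotypes.mean(axis=0)
    sd = genotypes.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (genotypes - mu) / sd
    window = window_kb * 1000.0
    ell = np.empty(m)
    start = 0
    for j in range(m):
        while start < j and (chrom[start] != chrom[j] or pos[j] - pos[start] > window):
            start += 1
        end = j
        while end + 1 < m and chrom[end + 1] == chrom[j] and pos[end + 1] - pos[j] <= window:
            end += 1
        block = Z[:, start:end + 1]
        r = block.T @ Z[:, j] / n
        r2 = r * r
        if adjusted:
            ell[j] = np.sum(r2 - (1.0 - r2) / (n - 2))
        else:
            ell[j] = np.sum(r2)
    return ell


def _jackknife(theta_fn, n_items: int, n_blocks: int = N_JACKKNIFE_BLOCKS):
    """Delete-one-block jackknife over contiguous index blocks."""
    edges = np.linspace(0, n_items, n_blocks + 1).astype(int)
    full = theta_fn(np.ones(n_items, dtype=bool))
    thetas = []
    for b in range(n_blocks):
        mask = np.ones(n_items, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        thetas.append(theta_fn(mask))
    thetas = np.asarray(thetas)
    mean = thetas.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((thetas - mean) ** 2, axis=0))
    return full, se


def _wls(x, y, w):
    X = np.column_stack([np.ones_like(x), x])
    Wx = X * w[:, None]
    coef = np.linalg.solve(X.T @ Wx, Wx.T @ y)
    return coef  # [intercept, slope]


def estimate_h2(ss: pd.DataFrame, ld_scores: np.ndarray, n: int, m: int | None = None) -> LdscFit:
    """SNP heritability and confounding intercept from summary stats.

    ``ss`` needs BETA and SE aligned with ``ld_scores``; chi-square is
    (beta/se)^2, retained up to :data:`CHI2_MAX`. Weights are
    1/max(l, 1). SEs by 20-block jackknife over contiguous variants.
    """
    ell = np.asarray(ld_scores, dtype=float)
    if m is None:
        m = len(ell)
    if m < MIN_VARIANTS:
        raise ValueError(f"need at least {MIN_VARIANTS} variants for a stable regression")
    if len(ss) != len(ell):
        raise ValueError("summary statistics and LD scores are not aligned")
    z = ss["BETA"].to_numpy(dtype=float) / ss["SE"].to_numpy(dtype=float)
    chi2 = np.minimum(z * z, CHI2_MAX)
    x = n * ell / m
    w = 1.0 / np.maximum(ell, 1.0)

    def theta(mask):
        return _wls(x[mask], chi2[mask], w[mask])

    (intercept, slope), (int_se, slope_se) = _jackknife(theta, len(ell))
    return LdscFit(h2=float(slope), h2_se=float(slope_se),
                   intercept=float(intercept), intercept_se=float(int_se))


def genetic_correlation(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    ld_scores: np.ndarray,
    n1: int,
    n2: int,
    n_overlap: int = 0,
    mask: np.ndarray | None = None,
    m: int | None = None,
) -> LdscFit:
    """Cross-trait LD score regression.

    Regresses z1*z2 on sqrt(n1*n2)*l/m (intercept free, absorbing sample
    overlap); the slope is the genetic covariance and
    rg = cov_g / sqrt(h2_1 * h2_2). Variants where ``mask`` is False
    (e.g. an MHC-like region) are excluded. Estimates outside [-1, 1]
    are tolerated to +/-1.25 and flagged.
    """
    ell = np.asarray(ld_scores, dtype=float)
    keep = np.ones(len(ell), dtype=bool) if mask is None else np.asarray(mask, bool)
    ss1, ss2, ell = ss1[keep].reset_index(drop=True), ss2[keep].reset_index(drop=True), ell[keep]
    if m is None:
        m = len(ell)
    fit1 = estimate_h2(ss1, ell, n1, m)
    fit2 = estimate_h2(ss2, ell, n2, m)
    if fit1.h2 <= 0 or fit2.h2 <= 0:
        out = LdscFit(h2=fit1.h2, h2_se=fit1.h2_se, intercept=fit1.intercept,
                      intercept_se=fit1.intercept_se, rg=None, rg_se=None)
        out.flagged = True
        return out

    z1 = ss1["BETA"].to_numpy(float) / ss1["SE"].to_numpy(float)
    z2 = ss2["BETA"].to_numpy(float) / ss2["SE"].to_numpy(float)
    zz = np.clip(z1 * z2, -CHI2_MAX, CHI2_MAX)
    x = np.sqrt(n1 * n2) * ell / m
    w = 1.0 / np.maximum(ell, 1.0)
    chi1 = np.minimum(z1 * z1, CHI2_MAX)
    chi2_ = np.minimum(z2 * z2, CHI2_MAX)
    x1 = n1 * ell / m
    x2 = n2 * ell / m

    def theta(msk):
        cov_g = _wls(x[msk], zz[msk], w[msk])[1]
        h1 = _wls(x1[msk], chi1[msk], w[msk])[1]
        h2 = _wls(x2[msk], chi2_[msk], w[msk])[1]
        denom = np.sqrt(max(h1, 1e-6) * max(h2, 1e-6))
        return np.array([cov_g / denom])

    (rg,), (rg_se,) = _jackknife(theta, len(ell))
    return LdscFit(
        h2=fit1.h2, h2_se=fit1.h2_se, intercept=fit1.intercept,
        intercept_se=fit1.intercept_se, rg=float(rg), rg_se=float(rg_se),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def rg_significance(fit: LdscFit) -> float:
    """Two-sided normal p-value for rg != 0 (jackknife SE)."""
    if fit.rg is None or fit.rg_se is None or fit.rg_se <= 0:
        return float("nan")
    return float(2 * stats.norm.sf(abs(fit.rg / fit.rg_se)))
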