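"""Replication machinery: proxy variants and fixed-effect meta-analysis.

Per-cohort associations of the novel leads (run with the replication
covariate set and an inverse-normal-transformed response) are pooled by
inverse-variance-weighted fixed-effect meta-analysis. Leads absent from
a replication panel are substituted by a proxy in LD (r^2 > 0.4 within
1.5 Mb in the reference panel), preferring the highest r^2 and breaking
ties by a fixed functional-consequence severity ordering. A locus
counts as replicated when the pooled p is below 0.05 (nominal, no
multiple-testing correction) and the pooled sign matches discovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .loci import ld_r2
from .gwas import run_gwas
from .synthcohort import Cohort

__all__ = [
    "MetaResult",
    "CONSEQUENCE_SEVERITY",
    "ivw_fixed",
    "find_proxy",
    "cohort_summary",
    "replicate",
]

# Fixed severity ordering for the proxy tie-break (most severe first).
CONSEQUENCE_SEVERITY = (
    "missense_variant",
    "splice_region_variant",
    "splice_polypyrimidine_tract_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "synonymous_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "regulatory_region_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)


def _severity_rank(consequence: str) -> int:
    try:
        return CONSEQUENCE_SEVERITY.index(consequence)
    except ValueError:
        return len(CONSEQUENCE_SEVERITY)


@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    weights: np.ndarray = field(default_factory=lambda: np.array([]))
    q: float = 0.0
    q_p: float = 1.0
    n_studies: int = 0

    def __post_init__(self):
        if self.q < 0:
            raise ValueError("Cochran Q must be non-negative")


def ivw_fixed(betas, ses) -> MetaResult:
    """Inverse-variance-weighted fixed-effect pooling.

    w_i = 1/se_i^2, pooled beta = sum(w b)/sum(w), pooled se =
    (sum w)^{-1/2}, two-sided normal p, Cochran Q = sum w (b_i - b)^2.
    A single study passes through with a warning.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no studies to pool")
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    if b.size == 1:
        warnings.warn("single study: pooled estimate is a passthrough")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    q = float(np.sum(w * (b - pooled) ** 2))
    q_p = float(stats.chi2.sf(q, df=max(b.size - 1, 1))) if b.size > 1 else 1.0
    return MetaResult(pooled, pooled_se, p, weights=w / np.sum(w), q=q, q_p=q_p,
                      n_studies=int(b.size))


def find_proxy(
    target_id: str,
    available_ids,
    ref_genotypes: np.ndarray,
    ref_variants: pd.DataFrame,
    r2_min: float = 0.4,
    window_mb: float = 1.5,
):
    """Resolve a variant in a replication panel, by identity or LD proxy.

    If the target is genotyped in the replication cohort it is its own
    proxy (r^2 = 1). Otherwise candidates are the available variants
    within +/- ``window_mb`` of the target in the reference panel with
    r^2 > ``r2_min``; the highest r^2 wins, ties broken by consequence
    severity then smaller position. Returns ``(proxy_id, r2)`` or
    ``None`` when the target is absent from the reference or no
    candidate qualifies.
    """
    available = set(available_ids)
    if target_id in available:
        return target_id, 1.0
    meta = ref_variants.set_index("id")
    if target_id not in meta.index:
        return None
    vidx = {v: i for i, v in enumerate(ref_variants["id"])}
    t_pos = int(meta.at[target_id, "pos"])
    t_chrom = str(meta.at[target_id, "chrom"])
    window = window_mb * 1e6
    best = None
    for cand in available:
        if cand not in meta.index or cand == target_id:
            continue
        if str(meta.at[cand, "chrom"]) != t_chrom:
            continue
        if abs(int(meta.at[cand, "pos"]) - t_pos) > window:
            continue
        r2 = ld_r2(ref_genotypes, vidx[target_id], vidx[cand])
        if r2 <= r2_min:
            continue
        key = (-r2, _severity_rank(str(meta.at[cand, "consequence"])),
               int(meta.at[cand, "pos"]))
        if best is None or key < best[0]:
            best = (key, cand, r2)
    if best is None:
        return None
    return best[1], best[2]


def cohort_summary(cohort: Cohort, trait: str, variant_ids: list[str], name: str) -> pd.DataFrame:
    """Association of the listed variants in one replication cohort,
    using the replication covariate set and INT response."""
    vidx = cohort.variant_index()
    mask = np.zeros(cohort.n_variants, dtype=bool)
    for v in variant_ids:
        mask[vidx[v]] = True
    ss = run_gwas(cohort, trait, adjustment="none", covariate_set="replication",
                  variant_mask=mask)
    ss = ss.copy()
    ss["COHORT"] = name
    return ss


def replicate(
    loci: pd.DataFrame,
    discovery_ss: pd.DataFrame,
    cohorts: list[Cohort],
    cohort_names: list[str] | None = None,
    trait: str = "liver_fat",
    reference: Cohort | None = None,
    r2_min: float = 0.4,
    window_mb: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Replication table for a set of (novel) loci across cohorts.

    Per locus: resolve the lead (or a proxy) in each cohort, run the
    per-cohort association, pool by IVW, and flag replication when the
    pooled p is below ``p_threshold`` *and* the pooled direction matches
    the discovery direction. Loci unresolvable in every cohort are
    reported as untested.
    """
    if cohort_names is None:
        cohort_names = [f"cohort{i+1}" for i in range(len(cohorts))]
    disc = discovery_ss.set_index("ID")
    rows = []
    for _, locus in loci.iterrows():
        lead = locus["LEAD_ID"]
        disc_row = disc.loc[lead]
        per_cohort = []
        proxies = []
        for cohort, cname in zip(cohorts, cohort_names):
            ref = reference if reference is not None else cohort
            resolved = find_proxy(lead, list(cohort.variants["id"]), ref.genotypes,
                                  ref.variants, r2_min, window_mb)
            if resolved is None:
                continue
            proxy_id, r2 = resolved
            ss = cohort_summary(cohort, trait, [proxy_id], cname)
            if ss.empty:
                continue
            row = ss.iloc[0]
            beta = float(row["BETA"])
            # harmonize the proxy's effect direction to the discovery lead:
            # for a proxy, the sign of the dosage correlation in the
            # reference panel orients the effect.
            if proxy_id == lead:
                if row["EA"] == disc_row["OA"]:
                    beta = -beta
            else:
                vidx = {v: i for i, v in enumerate(ref.variants["id"])}
                a = ref.genotypes[:, vidx[lead]]
                b = ref.genotypes[:, vidx[proxy_id]]
                if np.corrcoef(a, b)[0, 1] < 0:
                    beta = -beta
            per_cohort.append((cname, beta, float(row["SE"]), int(row["N"])))
            proxies.append(f"{cname}:{proxy_id}" + ("" if proxy_id == lead else f"(r2={r2:.2f})"))
        if not per_cohort:
            rows.append(
                {"LOCUS_ID": locus["LOCUS_ID"], "LEAD_ID": lead, "PROXY_ID": "",
                 "POOLED_BETA": np.nan, "POOLED_SE": np.nan, "P": np.nan,
                 "Q": np.nan, "N_COHORTS": 0, "REPLICATED": 0, "STATUS": "untested"}
            )
            continue
        res = ivw_fixed([c[1] for c in per_cohort], [c[2] for c in per_cohort])
        sign_ok = np.sign(res.beta) == np.sign(float(disc_row["BETA"]))
        replicated = bool(res.p < p_threshold and sign_ok)
        rows.append(
            {
                "LOCUS_ID": locus["LOCUS_ID"],
                "LEAD_ID": lead,
                "PROXY_ID": ";".join(proxies),
                "POOLED_BETA": res.beta,
                "POOLED_SE": res.se,
                "P": res.p,
                "Q": res.q,
                "N_COHORTS": res.n_studies,
                "REPLICATED": int(replicated),
                "STATUS": "tested",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["note"] = "replication p-values are nominal and not adjusted for multiple testing"
    return out
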