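"""Definition of statistically independent association loci.

Three stages mirror the discovery workflow: greedy LD clumping of
genome-wide-significant variants around p-value-ordered leads, forward
stepwise conditional-joint selection of clump leads with exact joint
regression on individual-level data, and a cross-adjustment pleiotropy
merge that assigns one locus id to leads from different adiposity
adjustments lying within 1 Mb and in LD (r^2 > 0.2), taking connected
components as the transitive closure of the pairwise rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .gwas import covariate_matrix, inverse_normal_transform
from .synthcohort import Cohort

__all__ = ["Locus", "Clump", "ld_r2", "clump", "conditional_select",
           "merge_pleiotropic", "loci_to_frame", "load_published_loci"]

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8


@dataclass
class Clump:
    lead_id: str
    member_ids: list
    lead_p: float
    lead_pos: int
    chrom: str


@dataclass
class Locus:
    locus_id: str
    lead_id: str
    chrom: str
    pos: int
    sources: list                  # adjustments contributing a lead
    lead_p: float
    lead_beta: float
    lead_se: float
    lead_ea: str
    lead_oa: str
    pleiotropic: bool
    members: list = field(default_factory=list)
    source_of_lead: str = ""


def ld_r2(genotypes: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of mean-imputed dosages."""
    a = genotypes[:, i].astype(float)
    b = genotypes[:, j].astype(float)
    for v in (a, b):
        nanmask = np.isnan(v)
        if nanmask.any():
            v[nanmask] = v[~nanmask].mean()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _sort_significant(sig: pd.DataFrame) -> pd.DataFrame:
    """Ascending p; ties broken by larger |beta| then smaller position."""
    return sig.assign(_ab=-sig["BETA"].abs()).sort_values(
        ["P", "_ab", "POS"], kind="mergesort"
    ).drop(columns="_ab")


def clump(
    ss: pd.DataFrame,
    genotypes: np.ndarray,
    variant_index: dict[str, int],
    p1: float = 5e-8,
    r2: float = 0.01,
    window_kb: float = 1000.0,
) -> list[Clump]:
    """Greedy LD clumping of significant variants.

    Sorts variants with p < ``p1`` by ascending p, repeatedly takes the
    best remaining as a lead and absorbs every unassigned significant
    variant within +/- ``window_kb`` of it with r^2 > ``r2``. The output
    partitions the significant set.
    """
    sig = _sort_significant(ss[ss["P"] < p1])
    if sig.empty:
        return []
    ids = sig["ID"].to_numpy()
    pos = sig["POS"].to_numpy()
    chrom = sig["CHR"].astype(str).to_numpy()
    pvals = sig["P"].to_numpy()
    window = window_kb * 1000.0
    assigned = np.zeros(len(sig), dtype=bool)
    clumps = []
    for k in range(len(sig)):
        if assigned[k]:
            continue
        assigned[k] = True
        members = [ids[k]]
        near = np.flatnonzero(
            ~assigned & (chrom == chrom[k]) & (np.abs(pos - pos[k]) <= window)
        )
        for j in near:
            if ld_r2(genotypes, variant_index[ids[k]], variant_index[ids[j]]) > r2:
                assigned[j] = True
                members.append(ids[j])
        clumps.append(Clump(ids[k], members, float(pvals[k]), int(pos[k]), chrom[k]))
    return clumps


def _joint_fit(y, C, G_sel):
    """Exact joint OLS of the transformed trait on covariates plus the
    selected dosages; returns per-variant beta, se, p."""
    X = np.column_stack([C, G_sel])
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("rank-deficient joint design")
    resid = y - X @ coef
    dof = n - k
    sigma2 = resid @ resid / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    m = G_sel.shape[1]
    return coef[-m:], se[-m:], p[-m:]


def conditional_select(
    cohort: Cohort,
    trait: str,
    adjustment: str,
    candidate_ids: list[str],
    window_mb: float = 10.0,
    p_threshold: float = 5e-8,
    transform: bool = True,
) -> pd.DataFrame:
    """Forward stepwise conditional-joint selection among clump leads.

    At each step the candidate with the smallest conditional p (joint OLS
    with covariates and the already-selected variants within the LD
    window) is added while that p stays below the genome-wide threshold.
    With individual-level genotypes the joint fit is exact. Returns the
    final joint-model effect estimates of the selected variants.
    """
    if not candidate_ids:
        return pd.DataFrame(columns=["ID", "CHR", "POS", "EA", "OA", "BETA_J", "SE_J", "P_J"])
    y = cohort.phenotypes[trait].to_numpy(dtype=float)
    if transform:
        y = inverse_normal_transform(y)
    C = covariate_matrix(cohort.phenotypes, adjustment)
    vidx = cohort.variant_index()
    meta = cohort.variants.set_index("id")
    pos = {v: int(meta.at[v, "pos"]) for v in candidate_ids}
    window = window_mb * 1e6
    G = cohort.genotypes

    selected: list[str] = []
    remaining = list(candidate_ids)
    while remaining:
        best = None
        for cand in remaining:
            cond = [s for s in selected if abs(pos[s] - pos[cand]) <= window]
            cols = [vidx[v] for v in cond + [cand]]
            try:
                _, _, p = _joint_fit(y, C, G[:, cols])
            except np.linalg.LinAlgError:
                log.warning("dropping %s: rank-deficient conditional design", cand)
                remaining = [v for v in remaining if v != cand]
                best = best  # re-evaluate loop with cand removed
                continue
            p_cand = p[-1]
            if best is None or p_cand < best[1]:
                best = (cand, p_cand)
        if best is None or best[1] >= p_threshold:
            break
        selected.append(best[0])
        remaining = [v for v in remaining if v != best[0]]

    if not selected:
        return pd.DataFrame(columns=["ID", "CHR", "POS", "EA", "OA", "BETA_J", "SE_J", "P_J"])
    cols = [vidx[v] for v in selected]
    beta, se, p = _joint_fit(y, C, G[:, cols])
    return pd.DataFrame(
        {
            "ID": selected,
            "CHR": [str(meta.at[v, "chrom"]) for v in selected],
            "POS": [pos[v] for v in selected],
            "EA": [meta.at[v, "ea"] for v in selected],
            "OA": [meta.at[v, "oa"] for v in selected],
            "BETA_J": beta,
            "SE_J": se,
            "P_J": p,
        }
    ).sort_values("POS", kind="mergesort").reset_index(drop=True)


def merge_pleiotropic(
    lead_tables: dict[str, pd.DataFrame],
    genotypes: np.ndarray,
    variant_index: dict[str, int],
    r2: float = 0.2,
    window_mb: float = 1.0,
) -> list[Locus]:
    """Merge per-adjustment lead lists into unified loci.

    Builds a graph over all lead variants with an edge whenever two leads
    are within ``window_mb`` and r^2 > ``r2``; connected components become
    one locus. The component lead is the minimum-p member across sources
    (ties: larger |beta|, then smaller position) and the pleiotropic flag
    is set when >= 2 adjustments contribute.

    Each table needs columns ID, CHR, POS, EA, OA, BETA, SE, P.
    """
    records = []
    for adj in sorted(lead_tables):
        t = lead_tables[adj]
        for _, row in t.iterrows():
            records.append(
                {
                    "adj": adj,
                    "id": row["ID"],
                    "chrom": str(row["CHR"]),
                    "pos": int(row["POS"]),
                    "ea": row["EA"],
                    "oa": row["OA"],
                    "beta": float(row["BETA"]),
                    "se": float(row["SE"]),
                    "p": float(row["P"]),
                }
            )
    if not records:
        return []
    window = window_mb * 1e6
    ids = sorted({r["id"] for r in records})
    info = {}
    for r in records:
        info.setdefault(r["id"], r)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1:]:
            ra, rb = info[a], info[b]
            if ra["chrom"] != rb["chrom"] or abs(ra["pos"] - rb["pos"]) > window:
                continue
            if ld_r2(genotypes, variant_index[a], variant_index[b]) > r2:
                graph.add_edge(a, b)

    per_id = {}
    for r in records:
        per_id.setdefault(r["id"], []).append(r)

    loci = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (info[c[0]]["chrom"], min(per_id[v][0]["pos"] for v in c)),
    )
    for comp in components:
        hits = [r for v in comp for r in per_id[v]]
        lead = min(hits, key=lambda r: (r["p"], -abs(r["beta"]), r["pos"]))
        sources = sorted({r["adj"] for r in hits})
        loci.append(
            Locus(
                locus_id="",
                lead_id=lead["id"],
                chrom=lead["chrom"],
                pos=lead["pos"],
                sources=sources,
                lead_p=lead["p"],
                lead_beta=lead["beta"],
                lead_se=lead["se"],
                lead_ea=lead["ea"],
                lead_oa=lead["oa"],
                pleiotropic=len(sources) >= 2,
                members=comp,
                source_of_lead=lead["adj"],
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.pos))
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"L{i:03d}"
    return loci


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "LOCUS_ID": [l.locus_id for l in loci],
            "LEAD_ID": [l.lead_id for l in loci],
            "CHR": [l.chrom for l in loci],
            "POS": [l.pos for l in loci],
            "EA": [l.lead_ea for l in loci],
            "OA": [l.lead_oa for l in loci],
            "BETA": [l.lead_beta for l in loci],
            "SE": [l.lead_se for l in loci],
            "SOURCES": [";".join(l.sources) for l in loci],
            "LEAD_P": [l.lead_p for l in loci],
            "LEAD_ADJ": [l.source_of_lead for l in loci],
            "PLEIOTROPIC": [int(l.pleiotropic) for l in loci],
            "MEMBERS": [";".join(l.members) for l in loci],
        }
    )


# ---------------------------------------------------------------------------
# Published locus table
# ---------------------------------------------------------------------------

def load_published_loci() -> pd.DataFrame:
    """Parse the shipped published locus table.

    The fixture preserves the printed trait tags verbatim (including
    their typographic quirks); this parser normalizes them into TRAIT
    (PDFF or cT1) and ADJ (none/BMI/WFM/VAT) columns and parses the
    p-values, including the '< x' underflow notation.
    """
    from importlib import resources

    path = resources.files("prspartition.data") / "published_loci.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    traits, adjs = [], []
    for label in df["TRAIT_LABEL"]:
        label = label.strip()
        trait = "PDFF" if label.startswith("PDFF") else "cT1"
        rest = label[len(trait):].strip().strip("()").strip()
        adj = {"": "none", "NA": "none"}.get(rest, rest)
        if adj not in {"none", "BMI", "WFM", "VAT"}:
            raise ValueError(f"unparseable adjustment tag in {label!r}")
        traits.append(trait)
        adjs.append(adj)
    df["TRAIT"] = traits
    df["ADJ"] = adjs
    df["P"] = [
        float(str(p).lstrip("<").strip()) for p in df["P"]
    ]
    return df
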