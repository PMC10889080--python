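"""Exact enrichment tests and the unweighted gene-evidence ranking.

One-sided Fisher tests (upper-tail hypergeometric) serve two uses: the
contrast of trait-derived locus sets against an annotation (e.g. which
fraction of inflammation-derived versus fat-derived novel loci associate
with liver cancer) and the overlap of PRS-mapped genes with liver-
upregulated differentially expressed genes. Candidate genes at each
locus are ranked by an unweighted sum over seven binary evidence
sources; the generators of those sources are upstream tools, so the
matrix is consumed precomputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EVIDENCE_SOURCES",
    "fisher_one_sided",
    "set_overlap_enrichment",
    "rank_genes",
]

EVIDENCE_SOURCES = (
    "positional",
    "eqtl_map",
    "chromatin",
    "gene_based",
    "colocalization",
    "finemap_nearest",
    "v2g",
)


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("grand total must be positive")
    return t


def fisher_one_sided(table) -> float:
    """Upper-tail exact test on the [0, 0] cell of a 2x2 table.

    P(X >= a) under the hypergeometric distribution with the observed
    margins fixed; the caller orients the table so that enrichment in
    the designated cell is the alternative.
    """
    t = _validate_table(table)
    a = t[0, 0]
    row1 = t[0].sum()
    col1 = t[:, 0].sum()
    total = t.sum()
    return float(stats.hypergeom.sf(a - 1, total, col1, row1))


def set_overlap_enrichment(set_a, set_b, universe):
    """2x2 membership table of two gene sets over a universe plus the
    one-sided p for over-representation of their overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(universe) - both - only_a - only_b
    table = np.array([[both, only_a], [only_b, neither]], dtype=np.int64)
    return table, fisher_one_sided(table)


def rank_genes(evidence: pd.DataFrame, loci=None) -> pd.DataFrame:
    """Top-ranked gene(s) per locus by unweighted evidence sum.

    ``evidence`` has columns GENE, LOCUS_ID and the seven binary source
    columns. All genes attaining the maximal row sum at a locus are
    reported, in alphabetical order. Output columns: LOCUS_ID, GENE,
    SCORE.
    """
    ev = evidence.copy()
    for col in EVIDENCE_SOURCES:
        if col not in ev.columns:
            raise ValueError(f"evidence matrix missing source column {col!r}")
        vals = ev[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"evidence column {col!r} must be binary")
    ev["SCORE"] = ev[list(EVIDENCE_SOURCES)].sum(axis=1)
    wanted = sorted(ev["LOCUS_ID"].unique()) if loci is None else list(loci)
    rows = []
    for locus in wanted:
        sub = ev[ev["LOCUS_ID"] == locus]
        if sub.empty:
            raise ValueError(f"locus {locus} has no candidate genes")
        top = sub["SCORE"].max()
        for gene in sorted(sub.loc[sub["SCORE"] == top, "GENE"]):
            rows.append({"LOCUS_ID": locus, "GENE": gene, "SCORE": int(top)})
    return pd.DataFrame(rows)
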