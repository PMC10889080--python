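"""Full and partitioned polygenic scores.

Loci are partitioned by the concordance of their effects on liver fat
versus circulating triglycerides after aligning every lead to its
liver-fat-raising allele: a significant negative triglyceride effect is
*discordant* (hepatic lipoprotein retention keeps lipid in the liver and
out of the circulation), a significant positive effect *concordant*
(systemic substrate flux feeds both pools), and leads with no nominal
triglyceride association are *excluded*. Scores are weighted allele
sums standardized within the scored sample; downstream associations are
logistic (cross-sectional) and Cox proportional-hazards (incident, with
prevalent cases excluded) per SD of score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import covariate_matrix, inverse_normal_transform, logistic_assoc, PerfectSeparation

__all__ = [
    "PARTITIONS",
    "partition_by_concordance",
    "build_prs",
    "score_samples",
    "variance_explained",
    "outcome_associations",
    "cox_prospective",
]

PARTITIONS = ("discordant", "concordant", "excluded")


def _harmonized_beta(row: pd.Series, ea: str, oa: str) -> float:
    """Effect of ``ea`` implied by a summary-stat row, flipping if the
    row's effect allele is the other allele."""
    if row["EA"] == ea and row["OA"] == oa:
        return float(row["BETA"])
    if row["EA"] == oa and row["OA"] == ea:
        return -float(row["BETA"])
    raise ValueError(f"alleles {row['EA']}/{row['OA']} cannot be harmonized to {ea}/{oa}")


def partition_by_concordance(
    liver_ss: pd.DataFrame,
    tg_ss: pd.DataFrame,
    loci: pd.DataFrame,
    tg_alpha: float = 0.05,
) -> pd.DataFrame:
    """Label each locus discordant / concordant / excluded.

    ``loci`` needs LOCUS_ID, LEAD_ID, EA, OA (lead alleles); both summary
    stat sets must contain every lead. The lead is aligned to its
    liver-fat-raising allele first, then classified by the sign of the
    triglyceride effect on that same allele (excluded when the TG p-value
    is above ``tg_alpha``).
    """
    liver = liver_ss.set_index("ID")
    tg = tg_ss.set_index("ID")
    missing = [v for v in loci["LEAD_ID"] if v not in tg.index]
    if missing:
        raise ValueError(f"missing TG association for lead(s): {', '.join(missing)}")
    missing = [v for v in loci["LEAD_ID"] if v not in liver.index]
    if missing:
        raise ValueError(f"missing liver association for lead(s): {', '.join(missing)}")

    rows = []
    for _, locus in loci.iterrows():
        vid, ea, oa = locus["LEAD_ID"], locus["EA"], locus["OA"]
        b_liver = _harmonized_beta(liver.loc[vid], ea, oa)
        b_tg = _harmonized_beta(tg.loc[vid], ea, oa)
        if b_liver < 0:   # align to the liver-fat-raising allele
            ea, oa = oa, ea
            b_liver, b_tg = -b_liver, -b_tg
        p_tg = float(tg.loc[vid, "P"])
        if p_tg >= tg_alpha:
            label = "excluded"
        elif b_tg < 0:
            label = "discordant"
        else:
            label = "concordant"
        rows.append(
            {
                "LOCUS_ID": locus["LOCUS_ID"],
                "ID": vid,
                "EA": ea,
                "OA": oa,
                "BETA_LIVER": b_liver,
                "BETA_TG": b_tg,
                "P_TG": p_tg,
                "PARTITION": label,
            }
        )
    return pd.DataFrame(rows)


def build_prs(
    partitioned: pd.DataFrame,
    weights: str = "discovery",
) -> pd.DataFrame:
    """PRS model table: aligned effect allele, non-negative weight,
    partition label and locus provenance.

    ``weights='discovery'`` uses the liver-fat discovery betas (aligned,
    hence >= 0); ``'equal'`` gives every variant unit weight.
    """
    if partitioned["ID"].duplicated().any():
        raise ValueError("duplicate variants in the PRS model")
    model = partitioned.rename(columns={"BETA_LIVER": "WEIGHT"})[
        ["ID", "EA", "OA", "WEIGHT", "PARTITION", "LOCUS_ID"]
    ].copy()
    if weights == "equal":
        model["WEIGHT"] = 1.0
    elif weights != "discovery":
        raise ValueError("weights must be 'discovery' or 'equal'")
    if (model["WEIGHT"] < 0).any():
        raise ValueError("weights must be non-negative after alignment")
    return model


def score_samples(
    genotypes: np.ndarray,
    variants: pd.DataFrame,
    model: pd.DataFrame,
    partition: str | None = None,
    max_missing: float = 0.2,
    standardize: bool = True,
) -> np.ndarray:
    """Per-sample weighted allele-dosage score.

    Model variants absent from the genotype panel are dropped with a
    warning; more than ``max_missing`` missing is an error. When
    ``partition`` is given only that partition's variants contribute.
    """
    use = model if partition is None else model[model["PARTITION"] == partition]
    if use.empty:
        raise ValueError(f"no variants in partition {partition!r}")
    vidx = {v: i for i, v in enumerate(variants["id"])}
    meta = variants.set_index("id")
    present = use[use["ID"].isin(vidx)]
    n_missing = len(use) - len(present)
    if n_missing:
        if n_missing / len(use) > max_missing:
            raise ValueError(
                f"{n_missing}/{len(use)} model variants missing from the genotype panel"
            )
        warnings.warn(f"dropping {n_missing} model variant(s) absent from the panel")
    score = np.zeros(genotypes.shape[0])
    for _, row in present.iterrows():
        j = vidx[row["ID"]]
        dose = genotypes[:, j].astype(float)
        nan = np.isnan(dose)
        if nan.any():
            dose[nan] = dose[~nan].mean()
        ea, oa = meta.at[row["ID"], "ea"], meta.at[row["ID"], "oa"]
        if row["EA"] == ea:
            pass
        elif row["EA"] == oa:
            dose = 2.0 - dose
        else:
            raise ValueError(f"allele mismatch for {row['ID']}")
        score += row["WEIGHT"] * dose
    if standardize:
        sd = score.std()
        score = (score - score.mean()) / (sd if sd > 0 else 1.0)
    return score


def variance_explained(score, trait, covariates: np.ndarray, transform: bool = True) -> float:
    """Incremental variance explained by the score, in percent:
    R^2(covariates + score) - R^2(covariates) from two nested OLS fits."""
    y = np.asarray(trait, dtype=float)
    if transform:
        y = inverse_normal_transform(y)
    s = np.asarray(score, dtype=float)

    def _r2(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - resid @ resid / tss

    base = _r2(covariates)
    full = _r2(np.column_stack([covariates, s]))
    return 100.0 * (full - base)


SENSITIVITY_SETS = {
    "primary": (),
    "metabolic": ("hypertension", "diabetes", "total_cholesterol", "alcohol"),
}


def outcome_associations(
    scores: dict[str, np.ndarray],
    pheno: pd.DataFrame,
    outcomes: list[str],
    extra_adjusters: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Logistic association of each standardized score with each binary
    outcome, adjusted for BMI, age, sex, the age polynomials, PCs and
    batch (plus any named sensitivity adjusters present in the table)."""
    C = covariate_matrix(pheno, adjustment="BMI")
    extra = [pheno[c].to_numpy(float) for c in extra_adjusters if c in pheno.columns]
    if extra:
        C = np.column_stack([C] + extra)
    rows = []
    for outcome in outcomes:
        y = pheno[outcome].to_numpy(dtype=float)
        if y.sum() == 0:
            warnings.warn(f"outcome {outcome}: zero events, skipped")
            continue
        for label, score in scores.items():
            try:
                res = logistic_assoc(score, y, C, name=f"{label}:{outcome}")
            except PerfectSeparation:
                warnings.warn(f"{label}:{outcome} perfectly separated, skipped")
                continue
            rows.append(
                {
                    "outcome": outcome,
                    "score": label,
                    "measure": "OR",
                    "estimate": res["or"],
                    "ci_low": res["ci_low"],
                    "ci_high": res["ci_high"],
                    "p": res["p"],
                    "n": res["n"],
                    "n_events": res["n_events"],
                    "adjustment_set": "+".join(("base",) + tuple(extra_adjusters)),
                }
            )
    return pd.DataFrame(rows)


def cox_prospective(
    scores: dict[str, np.ndarray],
    pheno: pd.DataFrame,
    outcomes: list[str],
) -> pd.DataFrame:
    """Cox proportional-hazards association of each score with incident
    disease; prevalent (baseline) cases are excluded before fitting.
    Ties are handled by the Breslow approximation and a Schoenfeld-type
    scaled-residual trend test is reported, not enforced.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    rows = []
    base = pd.DataFrame(
        covariate_matrix(pheno, adjustment="BMI")[:, 1:],  # drop the intercept
        index=pheno.index,
    )
    base.columns = [f"c{i}" for i in range(base.shape[1])]
    for outcome in outcomes:
        prevalent = pheno[f"{outcome}_prevalent"].astype(bool)
        keep = ~prevalent
        if pheno.loc[keep, f"{outcome}_event"].sum() == 0:
            warnings.warn(f"outcome {outcome}: no incident events, skipped")
            continue
        for label, score in scores.items():
            df = base.loc[keep].copy()
            df["score"] = np.asarray(score)[keep.to_numpy()]
            df["time"] = pheno.loc[keep, f"{outcome}_time"].to_numpy()
            df["event"] = pheno.loc[keep, f"{outcome}_event"].to_numpy()
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            beta = float(cph.params_["score"])
            se = float(cph.standard_errors_["score"])
            try:
                ph = proportional_hazard_test(cph, df, time_transform="rank")
                ph_p = float(ph.summary.loc["score", "p"])
            except Exception:  # diagnostic only; never fail the fit
                ph_p = float("nan")
            rows.append(
                {
                    "outcome": outcome,
                    "score": label,
                    "measure": "HR",
                    "estimate": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
                    "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
                    "p": float(cph.summary.loc["score", "p"]),
                    "n": int(keep.sum()),
                    "n_events": int(df["event"].sum()),
                    "ph_test_p": ph_p,
                    "adjustment_set": "base",
                }
            )
    return pd.DataFrame(rows)
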