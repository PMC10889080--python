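"""Partitioning, scoring and disease-association checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from prspartition.gwas import covariate_matrix
from prspartition.prs import (
    build_prs,
    cox_prospective,
    outcome_associations,
    partition_by_concordance,
    score_samples,
    variance_explained,
)


def _ss(rows):
    return pd.DataFrame(rows, columns=["ID", "EA", "OA", "BETA", "SE", "P"])


def _loci(rows):
    return pd.DataFrame(rows, columns=["LOCUS_ID", "LEAD_ID", "EA", "OA"])


LIVER = _ss([
    ["v1", "A", "G", 0.2, 0.01, 1e-20],
    ["v2", "A", "G", -0.2, 0.01, 1e-20],   # liver-raising allele is G
    ["v3", "A", "G", 0.2, 0.01, 1e-20],
])
TG = _ss([
    ["v1", "A", "G", -0.1, 0.01, 1e-6],    # discordant
    ["v2", "A", "G", -0.1, 0.01, 1e-6],    # aligned to G: +0.1 -> concordant
    ["v3", "A", "G", 0.05, 0.01, 0.4],     # not associated -> excluded
])
LOCI = _loci([["L001", "v1", "A", "G"], ["L002", "v2", "A", "G"], ["L003", "v3", "A", "G"]])


def test_partition_rules_by_construction():
    part = partition_by_concordance(LIVER, TG, LOCI)
    labels = dict(zip(part["ID"], part["PARTITION"]))
    assert labels == {"v1": "discordant", "v2": "concordant", "v3": "excluded"}
    # alignment: v2's effect allele becomes the liver-raising G
    row = part.set_index("ID").loc["v2"]
    assert row["EA"] == "G" and row["BETA_LIVER"] == pytest.approx(0.2)
    assert row["BETA_TG"] == pytest.approx(0.1)
    assert (part["BETA_LIVER"] >= 0).all()


def test_partition_is_exhaustive_and_exclusive():
    part = partition_by_concordance(LIVER, TG, LOCI)
    assert len(part) == len(LOCI)
    assert set(part["PARTITION"]) <= {"discordant", "concordant", "excluded"}
    model = build_prs(part)
    disc = set(model.loc[model["PARTITION"] == "discordant", "ID"])
    conc = set(model.loc[model["PARTITION"] == "concordant", "ID"])
    excl = set(model.loc[model["PARTITION"] == "excluded", "ID"])
    assert disc.isdisjoint(conc)
    assert disc | conc | excl == set(LOCI["LEAD_ID"])


def test_partition_invariant_to_strand_relabelling():
    def relabel(ss, which):
        ss = ss.copy()
        for vid in which:
            i = ss.index[ss["ID"] == vid][0]
            ss.loc[i, ["EA", "OA"]] = ss.loc[i, ["OA", "EA"]].to_numpy()
            ss.loc[i, "BETA"] = -ss.loc[i, "BETA"]
        return ss

    base = partition_by_concordance(LIVER, TG, LOCI)
    flipped = partition_by_concordance(relabel(LIVER, ["v1", "v3"]),
                                       relabel(TG, ["v1", "v2"]), LOCI)
    assert list(base["PARTITION"]) == list(flipped["PARTITION"])
    assert np.allclose(base["BETA_LIVER"], flipped["BETA_LIVER"])


def test_partition_missing_tg_lead_raises():
    with pytest.raises(ValueError, match="v3"):
        partition_by_concordance(LIVER, TG[TG["ID"] != "v3"], LOCI)


def test_tg_alpha_threshold_controls_exclusion():
    part = partition_by_concordance(LIVER, TG, LOCI, tg_alpha=0.5)
    assert dict(zip(part["ID"], part["PARTITION"]))["v3"] == "concordant"


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _tiny_panel():
    variants = pd.DataFrame(
        {"chrom": "1", "pos": [100, 200], "id": ["v1", "v2"],
         "ea": ["A", "C"], "oa": ["G", "T"], "maf": 0.3, "info": 1.0,
         "consequence": "intron_variant"}
    )
    G = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0]])
    return G, variants


def test_single_variant_raw_score():
    G, variants = _tiny_panel()
    model = pd.DataFrame({"ID": ["v1"], "EA": ["A"], "OA": ["G"], "WEIGHT": [1.0],
                          "PARTITION": ["discordant"], "LOCUS_ID": ["L001"]})
    raw = score_samples(G, variants, model, standardize=False)
    assert list(raw) == [2.0, 1.0, 0.0]


def test_score_invariant_to_allele_flip_in_panel():
    G, variants = _tiny_panel()
    model = pd.DataFrame({"ID": ["v1", "v2"], "EA": ["A", "C"], "OA": ["G", "T"],
                          "WEIGHT": [0.5, 0.2], "PARTITION": ["discordant"] * 2,
                          "LOCUS_ID": ["L001", "L002"]})
    base = score_samples(G, variants, model, standardize=False)
    flipped_panel = variants.copy()
    flipped_panel.loc[0, ["ea", "oa"]] = ["G", "A"]
    G2 = G.copy()
    G2[:, 0] = 2 - G2[:, 0]
    flipped = score_samples(G2, flipped_panel, model, standardize=False)
    assert np.allclose(base, flipped)


def test_score_missing_variant_policy():
    G, variants = _tiny_panel()
    model = pd.DataFrame({"ID": ["v1", "v2", "v3", "v4", "v5"],
                          "EA": ["A", "C", "A", "A", "A"],
                          "OA": ["G", "T", "G", "G", "G"],
                          "WEIGHT": [1.0] * 5, "PARTITION": ["discordant"] * 5,
                          "LOCUS_ID": list("abcde")})
    with pytest.raises(ValueError, match="missing"):
        score_samples(G, variants, model)
    with pytest.warns(UserWarning, match="dropping"):
        score_samples(G, variants, model.iloc[:2].assign(ID=["v1", "vX"]), max_missing=0.6)


def test_negative_weight_rejected():
    part = partition_by_concordance(LIVER, TG, LOCI)
    bad = part.copy()
    bad.loc[0, "BETA_LIVER"] = -0.1
    with pytest.raises(ValueError, match="non-negative"):
        build_prs(bad)


# ---------------------------------------------------------------------------
# Variance explained
# ---------------------------------------------------------------------------

def test_variance_explained_matches_nested_ols_oracle():
    rng = np.random.default_rng(0)
    n = 2000
    C = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
    s = rng.standard_normal(n)
    y = C[:, 1] + 0.3 * s + rng.standard_normal(n)
    got = variance_explained(s, y, C, transform=False)

    def r2(X):
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ b
        return 1 - r @ r / np.sum((y - y.mean()) ** 2)

    want = 100 * (r2(np.column_stack([C, s])) - r2(C))
    assert got == pytest.approx(want, abs=1e-10)
    assert got > 0


def test_variance_explained_null_and_monotone():
    rng = np.random.default_rng(1)
    n = 10_000
    C = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = C[:, 1] + rng.standard_normal(n)
    null_score = rng.standard_normal(n)
    inc = variance_explained(null_score, y, C, transform=False)
    assert abs(inc) < 0.2
    assert inc >= 0.0   # nested OLS: R2 never decreases


# ---------------------------------------------------------------------------
# Outcome associations
# ---------------------------------------------------------------------------

def test_permuted_score_or_ci_covers_one(small_cohort):
    rng = np.random.default_rng(3)
    score = rng.permutation(
        score_samples(
            small_cohort.genotypes, small_cohort.variants,
            pd.DataFrame({"ID": small_cohort.variants["id"].iloc[[5, 15]],
                          "EA": small_cohort.variants["ea"].iloc[[5, 15]],
                          "OA": small_cohort.variants["oa"].iloc[[5, 15]],
                          "WEIGHT": [0.2, 0.1], "PARTITION": ["discordant"] * 2,
                          "LOCUS_ID": ["a", "b"]}),
        )
    )
    res = outcome_associations({"null": score}, small_cohort.phenotypes,
                               ["liver_disease", "cvd", "diabetes"])
    assert len(res) == 3
    assert ((res["ci_low"] <= 1.0) & (res["ci_high"] >= 1.0)).all()


def test_sensitivity_adjusters_are_recorded(small_cohort):
    rng = np.random.default_rng(4)
    score = rng.standard_normal(small_cohort.n_samples)
    pheno = small_cohort.phenotypes.copy()
    pheno["total_cholesterol"] = rng.standard_normal(len(pheno))
    res = outcome_associations({"s": score}, pheno, ["cvd"],
                               extra_adjusters=("total_cholesterol",))
    assert res["adjustment_set"].iloc[0] == "base+total_cholesterol"


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

def _cox_pheno(n, true_loghr, seed, prevalence=0.05, horizon=15.0, rate=0.01):
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    hazard = rate * np.exp(true_loghr * score)
    t = rng.exponential(1 / hazard)
    pheno = pd.DataFrame(index=[f"S{i}" for i in range(n)])
    pheno["age"] = rng.uniform(40, 70, n)
    pheno["sex"] = rng.integers(0, 2, n)
    pheno["batch"] = rng.integers(0, 2, n)
    for i in range(1, 11):
        pheno[f"PC{i}"] = rng.standard_normal(n)
    pheno["BMI"] = rng.standard_normal(n)
    pheno["d_prevalent"] = (rng.random(n) < prevalence).astype(int)
    pheno["d_event"] = (t < horizon).astype(int)
    pheno["d_time"] = np.minimum(t, horizon)
    return score, pheno


def test_cox_recovers_true_log_hazard_ratio():
    score, pheno = _cox_pheno(5000, true_loghr=0.3, seed=0)
    res = cox_prospective({"score": score}, pheno, ["d"])
    row = res.iloc[0]
    assert row["n_events"] >= 200
    se = (np.log(row["ci_high"]) - np.log(row["estimate"])) / norm.isf(0.025)
    assert abs(np.log(row["estimate"]) - 0.3) < 2 * se


def test_cox_null_ci_covers_one_and_excludes_prevalent():
    score, pheno = _cox_pheno(3000, true_loghr=0.0, seed=1, prevalence=0.1)
    res = cox_prospective({"score": score}, pheno, ["d"])
    row = res.iloc[0]
    assert row["ci_low"] <= 1.0 <= row["ci_high"]
    assert row["n"] == int((1 - pheno["d_prevalent"]).sum())  # exact exclusion


def test_cox_skips_outcome_without_events():
    score, pheno = _cox_pheno(500, true_loghr=0.0, seed=2)
    pheno["d_event"] = 0
    with pytest.warns(UserWarning, match="no incident events"):
        res = cox_prospective({"score": score}, pheno, ["d"])
    assert res.empty


def test_logistic_and_cox_agree_in_sign(small_cohort):
    """On the same simulated cohort, cross-sectional OR and prospective HR
    for an informative score point the same way."""
    model = pd.DataFrame({"ID": small_cohort.variants["id"].iloc[[5]],
                          "EA": small_cohort.variants["ea"].iloc[[5]],
                          "OA": small_cohort.variants["oa"].iloc[[5]],
                          "WEIGHT": [1.0], "PARTITION": ["discordant"],
                          "LOCUS_ID": ["a"]})
    mech = small_cohort.mechanism
    assert mech.iloc[5]["class"] == "retention"
    score = score_samples(small_cohort.genotypes, small_cohort.variants, model)
    logit = outcome_associations({"s": score}, small_cohort.phenotypes, ["liver_disease"])
    cox = cox_prospective({"s": score}, small_cohort.phenotypes, ["liver_disease"])
    assert np.sign(np.log(logit["estimate"].iloc[0])) == np.sign(np.log(cox["estimate"].iloc[0]))
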