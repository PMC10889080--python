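"""Locus-definition checks: LD estimator, greedy clumping against a
brute-force oracle, stepwise conditional selection, pleiotropy merging."""

import numpy as np
import pandas as pd
import pytest

from prspartition.gwas import run_gwas
from prspartition.loci import (
    clump,
    conditional_select,
    ld_r2,
    load_published_loci,
    loci_to_frame,
    merge_pleiotropic,
)
from prspartition.synthcohort import Cohort, SimConfig, simulate_cohort, simulate_genotypes


def test_ld_r2_self_is_one(small_cohort):
    assert ld_r2(small_cohort.genotypes, 3, 3) == pytest.approx(1.0, abs=1e-12)


def test_ld_r2_matches_covariance_formula(small_cohort):
    G = small_cohort.genotypes
    for i, j in [(0, 1), (5, 7), (10, 250)]:
        a, b = G[:, i], G[:, j]
        want = (np.mean(a * b) - a.mean() * b.mean()) ** 2 / (a.var() * b.var())
        assert ld_r2(G, i, j) == pytest.approx(want, abs=1e-12)


def test_ld_r2_zero_variance_errors():
    G = np.column_stack([np.ones(50), np.random.default_rng(0).binomial(2, 0.3, 50)])
    with pytest.raises(ValueError, match="zero-variance"):
        ld_r2(G, 0, 1)


def test_cross_block_ld_near_zero(small_cohort):
    G = small_cohort.genotypes
    vals = [ld_r2(G, i, j) for i in range(0, 10) for j in range(10, 20)]
    assert np.mean(vals) <= 0.01


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def _toy_ss(ids, pos, p, beta=None, chrom="1"):
    m = len(ids)
    return pd.DataFrame(
        {
            "CHR": chrom, "POS": pos, "ID": ids, "EA": "A", "OA": "G",
            "EAF": 0.3, "BETA": beta if beta is not None else np.ones(m),
            "SE": 0.01, "P": p, "N": 1000, "TRAIT": "t", "ADJ": "none",
        }
    )


def test_clump_single_significant_variant():
    rng = np.random.default_rng(0)
    G = rng.binomial(2, 0.3, (500, 3)).astype(float)
    ss = _toy_ss(["a", "b", "c"], [100, 200, 300], [1e-9, 0.5, 0.5])
    out = clump(ss, G, {"a": 0, "b": 1, "c": 2})
    assert len(out) == 1
    assert out[0].lead_id == "a" and out[0].member_ids == ["a"]


def test_clump_absorbs_ld_partner_and_keeps_independent():
    rng = np.random.default_rng(1)
    a = rng.binomial(2, 0.3, 2000).astype(float)
    noise = rng.binomial(1, 0.02, 2000)
    b = np.clip(a + noise - rng.binomial(1, 0.02, 2000), 0, 2)  # near-perfect LD
    c = rng.binomial(2, 0.3, 2000).astype(float)
    G = np.column_stack([a, b, c])
    ss = _toy_ss(["A", "B", "C"], [1000, 2000, 500_000], [1e-12, 1e-9, 1e-10])
    out = clump(ss, G, {"A": 0, "B": 1, "C": 2})
    leads = {cl.lead_id: sorted(cl.member_ids) for cl in out}
    assert leads == {"A": ["A", "B"], "C": ["C"]}


def brute_force_clump(ss, G, vidx, p1, r2, window_kb):
    """Independent reimplementation: repeatedly extract the global
    minimum-p unassigned variant and its LD window partners."""
    sig = ss[ss["P"] < p1].copy()
    sig["absbeta"] = sig["BETA"].abs()
    remaining = {
        row.ID: row for row in sig.itertuples()
    }
    result = []
    while remaining:
        lead = min(remaining.values(), key=lambda r: (r.P, -r.absbeta, r.POS))
        members = [lead.ID]
        del remaining[lead.ID]
        for other in list(remaining.values()):
            if str(other.CHR) != str(lead.CHR):
                continue
            if abs(other.POS - lead.POS) > window_kb * 1000:
                continue
            g1, g2 = G[:, vidx[lead.ID]], G[:, vidx[other.ID]]
            if np.corrcoef(g1, g2)[0, 1] ** 2 > r2:
                members.append(other.ID)
                del remaining[other.ID]
        result.append((lead.ID, sorted(members)))
    return sorted(result)


def test_clump_matches_brute_force_on_random_instances():
    """Greedy clumping equals the brute-force oracle on 100 random
    instances with up to 15 significant variants; output partitions the
    significant set."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 16))
        n = 300
        # random LD: latent factor mixture makes some pairs correlated
        k = int(rng.integers(1, 4))
        L = rng.standard_normal((n, k))
        W = rng.normal(0, 1, (k, m)) * rng.binomial(1, 0.5, (k, m))
        latent = L @ W + rng.standard_normal((n, m))
        G = (latent > rng.normal(0, 0.3, m)).astype(float) + (
            latent > rng.normal(0.5, 0.3, m)
        ).astype(float)
        G += rng.normal(0, 1e-6, G.shape)  # avoid zero-variance columns
        pos = np.sort(rng.integers(1, 3_000_000, m))
        p = 10.0 ** rng.uniform(-20, -5, m)
        ss = _toy_ss([f"v{i}" for i in range(m)], pos, p, beta=rng.normal(0, 1, m))
        vidx = {f"v{i}": i for i in range(m)}
        r2_thr, window = 0.1, 500.0
        got = clump(ss, G, vidx, p1=5e-8, r2=r2_thr, window_kb=window)
        want = brute_force_clump(ss, G, vidx, 5e-8, r2_thr, window)
        assert sorted((c.lead_id, sorted(c.member_ids)) for c in got) == want
        # partition property
        sig_ids = set(ss.loc[ss["P"] < 5e-8, "ID"])
        seen = [v for c in got for v in c.member_ids]
        assert sorted(seen) == sorted(sig_ids)


def test_clump_empty_when_nothing_significant():
    rng = np.random.default_rng(2)
    G = rng.binomial(2, 0.3, (100, 2)).astype(float)
    ss = _toy_ss(["a", "b"], [1, 2], [0.1, 0.2])
    assert clump(ss, G, {"a": 0, "b": 1}) == []


# ---------------------------------------------------------------------------
# Conditional-joint selection
# ---------------------------------------------------------------------------

def _synthetic_cohort_for_cojo(seed, beta1=0.2, beta2=0.15, pair_r=0.22, proxy=False):
    """Two markers in controlled LD plus independent fill, with the trait
    built from known per-SD effects."""
    rng = np.random.default_rng(seed)
    n = 6000
    z1 = rng.standard_normal(n)
    mix = pair_r
    z2 = mix * z1 + np.sqrt(1 - mix**2) * rng.standard_normal(n)
    t = 0.0  # maf ~ 0.5
    g1 = (z1 > t).astype(float) + (rng.standard_normal(n) > t)
    g2 = (z2 > t).astype(float) + (rng.standard_normal(n) > t) if not proxy else None
    if proxy:
        flip = rng.random(n) < 0.02
        g2 = np.where(flip, 2 - g1, g1).astype(float)
    g3 = rng.binomial(2, 0.4, n).astype(float)
    G = np.column_stack([g1, g2, g3])
    gs = (G - G.mean(0)) / G.std(0)
    y = beta1 * gs[:, 0] + (0.0 if proxy else beta2 * gs[:, 1]) + rng.standard_normal(n)
    variants = pd.DataFrame(
        {
            "chrom": "1", "pos": [1_000_000, 1_050_000, 9_000_000],
            "id": ["g1", "g2", "g3"], "ea": "A", "oa": "G",
            "maf": 0.5, "info": 1.0, "consequence": "intron_variant",
        }
    )
    pheno = {"liver_fat": y, "tg": rng.standard_normal(n),
             "age": rng.uniform(40, 70, n), "sex": rng.integers(0, 2, n),
             "batch": rng.integers(0, 2, n)}
    for i in range(1, 11):
        pheno[f"PC{i}"] = rng.standard_normal(n)
    for name in ("VAT", "WFM", "BMI", "WHR", "IWB"):
        pheno[name] = rng.standard_normal(n)
    return Cohort(G, variants, pd.DataFrame(pheno, index=[f"S{i}" for i in range(n)]))


def test_conditional_select_keeps_two_weak_ld_causals():
    cohort = _synthetic_cohort_for_cojo(0)
    sel = conditional_select(cohort, "liver_fat", "none", ["g1", "g2", "g3"])
    assert set(sel["ID"]) == {"g1", "g2"}
    # joint betas within 2 SE of the simulated per-allele truth
    gs_sd = cohort.genotypes.std(0)
    truth = {"g1": 0.2 / gs_sd[0], "g2": 0.15 / gs_sd[1]}
    for row in sel.itertuples():
        assert abs(row.BETA_J - truth[row.ID]) < 2 * row.SE_J


def test_conditional_select_drops_pure_proxy():
    cohort = _synthetic_cohort_for_cojo(1, proxy=True)
    assert ld_r2(cohort.genotypes, 0, 1) > 0.9
    sel = conditional_select(cohort, "liver_fat", "none", ["g1", "g2"])
    assert len(sel) == 1


def test_conditional_select_stops_at_threshold():
    cohort = _synthetic_cohort_for_cojo(2, beta1=0.0, beta2=0.0)
    sel = conditional_select(cohort, "liver_fat", "none", ["g1", "g2", "g3"])
    assert sel.empty


# ---------------------------------------------------------------------------
# Pleiotropy merge
# ---------------------------------------------------------------------------

def _leads(rows):
    return pd.DataFrame(rows, columns=["ID", "CHR", "POS", "EA", "OA", "BETA", "SE", "P"])


def _chain_genotypes(n=4000, seed=0):
    """A-B and B-C in LD (r2 ~ 0.3), A-C weak (r2 ~ 0.05)."""
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n)
    a = 0.25 * shared + rng.standard_normal(n)
    c = 0.25 * shared + rng.standard_normal(n)
    b = 0.52 * (a + c) + 0.58 * rng.standard_normal(n)
    G = np.column_stack([1 + 0.3 * a, 1 + 0.3 * b, 1 + 0.3 * c])
    return np.clip(G, 0, 2)


def test_merge_identical_lead_across_adjustments():
    G = _chain_genotypes()
    row = ["A", "1", 1000, "A", "G", 0.1, 0.01, 1e-10]
    row2 = ["A", "1", 1000, "A", "G", 0.11, 0.01, 1e-12]
    loci = merge_pleiotropic({"none": _leads([row]), "BMI": _leads([row2])},
                             G, {"A": 0, "B": 1, "C": 2})
    assert len(loci) == 1
    assert loci[0].sources == ["BMI", "none"]
    assert loci[0].pleiotropic
    assert loci[0].lead_p == 1e-12  # smaller p wins


def test_merge_chain_transitive_closure():
    G = _chain_genotypes()
    r_ab = ld_r2(G, 0, 1)
    r_bc = ld_r2(G, 1, 2)
    r_ac = ld_r2(G, 0, 2)
    assert r_ab > 0.2 and r_bc > 0.2 and r_ac < 0.2
    tables = {
        "none": _leads([["A", "1", 1000, "A", "G", 0.1, 0.01, 1e-10]]),
        "BMI": _leads([["B", "1", 2000, "A", "G", 0.1, 0.01, 1e-9]]),
        "VAT": _leads([["C", "1", 3000, "A", "G", 0.1, 0.01, 1e-8]]),
    }
    loci = merge_pleiotropic(tables, G, {"A": 0, "B": 1, "C": 2})
    assert len(loci) == 1
    assert sorted(loci[0].members) == ["A", "B", "C"]


def test_merge_window_rule_binds_despite_ld():
    G = _chain_genotypes()
    tables = {
        "none": _leads([["A", "1", 1_000_000, "A", "G", 0.1, 0.01, 1e-10]]),
        "BMI": _leads([["B", "1", 3_000_000, "A", "G", 0.1, 0.01, 1e-9]]),
    }
    loci = merge_pleiotropic(tables, G, {"A": 0, "B": 1, "C": 2})
    assert len(loci) == 2   # 2 Mb apart: never merged even in strong LD


def test_merge_invariant_to_adjustment_order():
    G = _chain_genotypes()
    t1 = {
        "none": _leads([["A", "1", 1000, "A", "G", 0.1, 0.01, 1e-10]]),
        "BMI": _leads([["B", "1", 2000, "A", "G", -0.2, 0.01, 1e-9]]),
    }
    t2 = dict(reversed(list(t1.items())))
    f1 = loci_to_frame(merge_pleiotropic(t1, G, {"A": 0, "B": 1, "C": 2}))
    f2 = loci_to_frame(merge_pleiotropic(t2, G, {"A": 0, "B": 1, "C": 2}))
    pd.testing.assert_frame_equal(f1, f2)


def test_merged_locus_count_recovers_simulated_architecture():
    """With well-separated causal blocks and strong effects, the merged
    locus count equals the causal block count in >= 90% of replicates."""
    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        cfg = SimConfig(n_samples=4000, n_blocks=8, variants_per_block=5,
                        n_retention=2, n_flux=2, n_liver_only=0,
                        beta_liver={"retention": 0.3, "flux": 0.3, "liver_only": 0.1},
                        beta_tg={"retention": -0.1, "flux": 0.1, "liver_only": 0.0},
                        outcome_models={}, seed=100 + seed)
        cohort = simulate_cohort(cfg)
        vidx = cohort.variant_index()
        tables = {}
        for adj in ("none", "BMI"):
            ss = run_gwas(cohort, "liver_fat", adj)
            clumps = clump(ss, cohort.genotypes, vidx)
            sel = conditional_select(cohort, "liver_fat", adj, [c.lead_id for c in clumps])
            marg = ss.set_index("ID")
            sel["BETA"] = [marg.at[v, "BETA"] for v in sel["ID"]]
            sel["SE"] = [marg.at[v, "SE"] for v in sel["ID"]]
            sel["P"] = [marg.at[v, "P"] for v in sel["ID"]]
            tables[adj] = sel
        merged = merge_pleiotropic(tables, cohort.genotypes, vidx)
        if len(merged) == 4:
            hits += 1
    assert hits >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# Published locus table
# ---------------------------------------------------------------------------

def test_published_table_parses_and_normalizes():
    df = load_published_loci()
    assert len(df) == 55
    assert set(df["TRAIT"]) == {"PDFF", "cT1"}
    assert set(df["ADJ"]) <= {"none", "BMI", "WFM", "VAT"}
    assert (df["P"] > 0).all() and (df["P"] < 5e-8).all()
    assert df["NOVEL"].isin([0, 1]).all()
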