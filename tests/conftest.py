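"""Shared fixtures: cohorts at the study scale and an LD panel for the
heritability regression, built once per session."""

import numpy as np
import pandas as pd
import pytest

from prspartition import gwas as gwas_mod
from prspartition.ldsc import compute_ld_scores
from prspartition.synthcohort import SimConfig, simulate_cohort, simulate_genotypes, standardize_genotypes


@pytest.fixture(scope="session")
def small_cohort():
    """Quick 2,500-sample cohort with the default mechanism classes."""
    cfg = SimConfig(n_samples=2500, n_blocks=30, variants_per_block=10, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_cohort():
    """The full-scale study cohort: 20,000 samples, 40 LD blocks x 30
    variants, 10 retention / 13 flux / 3 liver-only causal variants."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def demo_qc(demo_cohort):
    keep, _ = gwas_mod.qc_filter(demo_cohort.variants, demo_cohort.genotypes)
    return keep


@pytest.fixture(scope="session")
def ldsc_panel():
    """Genotype panel for LD-score regression checks: 5,000 samples,
    5,000 variants in 250 blocks with heterogeneous LD strength."""
    cfg = SimConfig(
        n_samples=5000, n_blocks=250, variants_per_block=20,
        n_retention=0, n_flux=0, n_liver_only=0,
        ar1_rho_range=(0.2, 0.97), seed=11,
    )
    G, variants = simulate_genotypes(cfg)
    Gs = standardize_genotypes(G)
    ell = compute_ld_scores(G, variants["pos"].to_numpy(), window_kb=1000.0)
    return {"G": G, "Gs": Gs, "variants": variants, "ell": ell}


def marginal_sumstats(Gs: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Correlation-scale marginal association statistics for a
    standardized genotype matrix (used by the LDSC checks)."""
    n = len(y)
    yz = (y - y.mean()) / y.std()
    r = Gs.T @ yz / n
    return pd.DataFrame({"BETA": r, "SE": np.full(Gs.shape[1], 1 / np.sqrt(n))})
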