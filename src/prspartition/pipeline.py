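"""End-to-end orchestration: simulate -> QC -> multi-adjustment GWAS ->
clump -> conditional-joint selection -> pleiotropy merge -> LD score
regression -> concordance partition and PRS associations -> replication
meta-analysis -> report.

Every stage reads its inputs from, and writes its outputs to, plain TSV
files under the run directory, so a run is resumable from any retained
intermediate and two runs with the same configuration are byte-identical
(checked via the sha256 manifest the report stage writes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from . import ldsc as ldsc_mod
from . import loci as loci_mod
from . import meta as meta_mod
from . import prs as prs_mod
from .synthcohort import Cohort, SimConfig, read_cohort, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; the thresholds default to the discovery
    workflow's published constants."""

    sim: SimConfig = field(default_factory=SimConfig)
    adjustments: tuple = ("none", "BMI", "WFM", "VAT")
    gwas_p: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 1000.0
    cojo_window_mb: float = 10.0
    merge_r2: float = 0.2
    merge_window_mb: float = 1.0
    proxy_r2: float = 0.4
    proxy_window_mb: float = 1.5
    qc_maf: float = 0.01
    qc_info: float = 0.8
    qc_hwe_p: float = 1e-10
    tg_alpha: float = 0.05
    ld_window_kb: float = 1000.0
    n_replication_cohorts: int = 4
    replication_n: int = 1000
    replication_variant_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self):
        for name in ("gwas_p", "clump_r2", "clump_window_kb", "cojo_window_mb",
                     "merge_r2", "merge_window_mb", "proxy_r2", "proxy_window_mb",
                     "qc_maf", "qc_info", "qc_hwe_p", "tg_alpha", "ld_window_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bad = [a for a in self.adjustments if a not in gwas_mod.ADJUSTMENTS]
        if bad:
            raise ValueError(f"unknown adjustment(s): {bad}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "seed" in raw and "seed" not in sim_raw:
            sim_raw["seed"] = raw["seed"]
        if "maf_range" in sim_raw:
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        if "adjustments" in raw:
            raw["adjustments"] = tuple(raw["adjustments"])
        return cls(sim=SimConfig(**sim_raw), **raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: str, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", **kw)


def _cohort_dir(outdir):
    return os.path.join(outdir, "cohort")


def _load_cohort(outdir) -> Cohort:
    return read_cohort(_cohort_dir(outdir))


def _qc_mask(outdir, cohort) -> np.ndarray:
    qc = pd.read_csv(os.path.join(outdir, "qc_variants.tsv"), sep="\t")
    keep_ids = set(qc.loc[qc["KEEP"] == 1, "ID"])
    return cohort.variants["id"].isin(keep_ids).to_numpy()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: str) -> None:
    cohort = simulate_cohort(cfg.sim)
    write_cohort(cohort, _cohort_dir(outdir))
    log.info("simulate: %d samples x %d variants", cohort.n_samples, cohort.n_variants)


def stage_qc(cfg: PipelineConfig, outdir: str) -> None:
    cohort = _load_cohort(outdir)
    keep, reasons = gwas_mod.qc_filter(
        cohort.variants, cohort.genotypes, cfg.qc_maf, cfg.qc_info, cfg.qc_hwe_p
    )
    _write(
        pd.DataFrame({"ID": cohort.variants["id"], "KEEP": keep.astype(int)}),
        os.path.join(outdir, "qc_variants.tsv"),
    )
    with open(os.path.join(outdir, "qc_summary.json"), "w") as fh:
        json.dump({"kept": int(keep.sum()), "excluded": reasons}, fh, sort_keys=True)
    log.info("qc: kept %d / %d variants (%s)", keep.sum(), len(keep), reasons)


def stage_gwas(cfg: PipelineConfig, outdir: str) -> None:
    cohort = _load_cohort(outdir)
    mask = _qc_mask(outdir, cohort)
    for adj in cfg.adjustments:
        ss = gwas_mod.run_gwas(cohort, "liver_fat", adjustment=adj, variant_mask=mask)
        gwas_mod.write_sumstats(ss, os.path.join(outdir, f"gwas_liver_fat_{adj}.tsv"))
    tg = gwas_mod.run_gwas(cohort, "tg", adjustment="none", variant_mask=mask)
    gwas_mod.write_sumstats(tg, os.path.join(outdir, "gwas_tg_none.tsv"))
    log.info("gwas: liver_fat x %s + tg", list(cfg.adjustments))


def stage_loci(cfg: PipelineConfig, outdir: str) -> None:
    cohort = _load_cohort(outdir)
    vidx = cohort.variant_index()
    for adj in cfg.adjustments:
        ss = gwas_mod.read_sumstats(os.path.join(outdir, f"gwas_liver_fat_{adj}.tsv"))
        clumps = loci_mod.clump(ss, cohort.genotypes, vidx, cfg.gwas_p,
                                cfg.clump_r2, cfg.clump_window_kb)
        sel = loci_mod.conditional_select(
            cohort, "liver_fat", adj, [c.lead_id for c in clumps],
            cfg.cojo_window_mb, cfg.gwas_p,
        )
        marg = ss.set_index("ID")
        if not sel.empty:
            sel["BETA"] = [float(marg.at[v, "BETA"]) for v in sel["ID"]]
            sel["SE"] = [float(marg.at[v, "SE"]) for v in sel["ID"]]
            sel["P"] = [float(marg.at[v, "P"]) for v in sel["ID"]]
        else:
            sel = sel.assign(BETA=[], SE=[], P=[])
        _write(sel, os.path.join(outdir, f"leads_{adj}.tsv"))
        log.info("loci[%s]: %d clumps -> %d independent leads", adj, len(clumps), len(sel))


def stage_merge(cfg: PipelineConfig, outdir: str) -> None:
    cohort = _load_cohort(outdir)
    tables = {}
    for adj in cfg.adjustments:
        t = pd.read_csv(os.path.join(outdir, f"leads_{adj}.tsv"), sep="\t",
                        dtype={"CHR": str})
        if not t.empty:
            tables[adj] = t
    merged = loci_mod.merge_pleiotropic(
        tables, cohort.genotypes, cohort.variant_index(), cfg.merge_r2, cfg.merge_window_mb
    )
    _write(loci_mod.loci_to_frame(merged), os.path.join(outdir, "loci_merged.tsv"))
    log.info("merge: %d unified loci", len(merged))


def stage_ldsc(cfg: PipelineConfig, outdir: str) -> None:
    cohort = _load_cohort(outdir)
    mask = _qc_mask(outdir, cohort)
    G = cohort.genotypes[:, mask]
    pos = cohort.variants.loc[mask, "pos"].to_numpy()
    ell = ldsc_mod.compute_ld_scores(G, pos, cfg.ld_window_kb)
    _write(pd.DataFrame({"ID": cohort.variants.loc[mask, "id"], "L2": ell}),
           os.path.join(outdir, "ld_scores.tsv"))
    rows = []
    m = int(mask.sum())
    for adj in cfg.adjustments:
        ss = gwas_mod.read_sumstats(os.path.join(outdir, f"gwas_liver_fat_{adj}.tsv"))
        try:
            fit = ldsc_mod.estimate_h2(ss, ell, int(ss["N"].iloc[0]), m)
            rows.append({"TRAIT": "liver_fat", "ADJ": adj, "H2": fit.h2,
                         "H2_SE": fit.h2_se, "INTERCEPT": fit.intercept,
                         "INTERCEPT_SE": fit.intercept_se})
        except ValueError as exc:
            log.warning("ldsc[%s]: %s", adj, exc)
    _write(pd.DataFrame(rows), os.path.join(outdir, "ldsc_fits.tsv"))


def stage_prs(cfg: PipelineConfig, outdir: str) -> None:
    cohort = _load_cohort(outdir)
    merged = pd.read_csv(os.path.join(outdir, "loci_merged.tsv"), sep="\t",
                         dtype={"CHR": str})
    if merged.empty:
        raise RuntimeError("no merged loci: cannot build a PRS")
    # liver-fat effect of each lead, from the adjustment that produced it
    liver_ss = merged.rename(columns={"LEAD_ID": "ID", "LEAD_P": "P"})[
        ["ID", "EA", "OA", "BETA", "SE", "P"]
    ]
    tg_ss = gwas_mod.read_sumstats(os.path.join(outdir, "gwas_tg_none.tsv"))
    part = prs_mod.partition_by_concordance(liver_ss, tg_ss, merged, cfg.tg_alpha)
    model = prs_mod.build_prs(part)
    _write(model, os.path.join(outdir, "prs_model.tsv"))

    scores = {"full": prs_mod.score_samples(cohort.genotypes, cohort.variants, model)}
    for label in ("discordant", "concordant"):
        if (model["PARTITION"] == label).any():
            scores[label] = prs_mod.score_samples(
                cohort.genotypes, cohort.variants, model, partition=label
            )
    C = gwas_mod.covariate_matrix(cohort.phenotypes, adjustment="BMI")
    r2_rows = [
        {"SCORE": label, "TRAIT": "liver_fat",
         "INCREMENTAL_R2_PCT": prs_mod.variance_explained(s, cohort.phenotypes["liver_fat"], C)}
        for label, s in scores.items()
    ]
    _write(pd.DataFrame(r2_rows), os.path.join(outdir, "prs_r2.tsv"))

    outcomes = [d for d in cfg.sim.outcome_models]
    assoc = prs_mod.outcome_associations(scores, cohort.phenotypes, outcomes)
    _write(assoc, os.path.join(outdir, "prs_assoc.tsv"))
    cox = prs_mod.cox_prospective(scores, cohort.phenotypes, outcomes)
    _write(cox, os.path.join(outdir, "prs_cox.tsv"))
    log.info("prs: %s", {k: int((model['PARTITION'] == k).sum()) for k in prs_mod.PARTITIONS})


def stage_meta(cfg: PipelineConfig, outdir: str) -> None:
    cohort = _load_cohort(outdir)
    merged = pd.read_csv(os.path.join(outdir, "loci_merged.tsv"), sep="\t",
                         dtype={"CHR": str})
    discovery_ss = merged.rename(columns={"LEAD_ID": "ID", "LEAD_P": "P"})[
        ["ID", "EA", "OA", "BETA", "SE", "P"]
    ]
    rng = np.random.default_rng([cfg.seed, 77])
    cohorts, names = [], []
    for i in range(cfg.n_replication_cohorts):
        rep_cfg = dataclasses.replace(
            cfg.sim, n_samples=cfg.replication_n, seed=int(rng.integers(2**31 - 1))
        )
        rep = simulate_cohort(rep_cfg)
        # replication panels are genotyped on sparser arrays: drop a
        # random subset of variants so the proxy rule is exercised
        keep = rng.random(rep.n_variants) < cfg.replication_variant_fraction
        rep = Cohort(
            rep.genotypes[:, keep],
            rep.variants.loc[keep].reset_index(drop=True),
            rep.phenotypes,
            None,
        )
        cohorts.append(rep)
        names.append(f"sim_rep{i+1}")
    table = meta_mod.replicate(
        merged, discovery_ss, cohorts, names, trait="liver_fat",
        reference=cohort, r2_min=cfg.proxy_r2, window_mb=cfg.proxy_window_mb,
    )
    _write(table, os.path.join(outdir, "replication.tsv"))
    log.info("meta: %d/%d loci replicated", int(table["REPLICATED"].sum()), len(table))


def stage_report(cfg: PipelineConfig, outdir: str) -> None:
    qc = json.load(open(os.path.join(outdir, "qc_summary.json")))
    merged = pd.read_csv(os.path.join(outdir, "loci_merged.tsv"), sep="\t")
    model = pd.read_csv(os.path.join(outdir, "prs_model.tsv"), sep="\t")
    r2 = pd.read_csv(os.path.join(outdir, "prs_r2.tsv"), sep="\t")
    rep = pd.read_csv(os.path.join(outdir, "replication.tsv"), sep="\t")
    lines = [
        "partitioned-PRS pipeline summary",
        f"seed: {cfg.seed}",
        f"variants kept after QC: {qc['kept']} (excluded {qc['excluded']})",
        f"merged independent loci: {len(merged)} "
        f"(pleiotropic: {int(merged['PLEIOTROPIC'].sum())})",
        "partition sizes: "
        + ", ".join(f"{k}={int((model['PARTITION'] == k).sum())}" for k in prs_mod.PARTITIONS),
        "incremental R2 (%): "
        + ", ".join(f"{r.SCORE}={r.INCREMENTAL_R2_PCT:.2f}" for r in r2.itertuples()),
        f"replicated loci: {int(rep['REPLICATED'].sum())}/{len(rep)} "
        "(nominal p<0.05, sign-consistent; not adjusted for multiple testing)",
    ]
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")

    manifest = {"parameters": {
        k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
        for k, v in dataclasses.asdict(cfg).items()
    }}
    checksums = {}
    for root, _, files in os.walk(outdir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            path = os.path.join(root, f)
            checksums[os.path.relpath(path, outdir)] = _sha256(path)
    manifest["checksums"] = checksums
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "gwas": stage_gwas,
    "loci": stage_loci,
    "merge": stage_merge,
    "ldsc": stage_ldsc,
    "prs": stage_prs,
    "meta": stage_meta,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, outdir: str, stages: list[str] | None = None) -> str:
    """Run the pipeline (or a downstream subset of stages) into
    ``outdir``; returns the path of the manifest. A failing stage aborts
    with the stage named; upstream outputs are retained."""
    os.makedirs(outdir, exist_ok=True)
    order = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in order if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    for name in order:
        try:
            STAGES[name](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return os.path.join(outdir, "manifest.json")
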