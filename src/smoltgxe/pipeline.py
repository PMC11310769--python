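"""End-to-end orchestration: simulate (or ingest) -> QC -> parentage ->
relationship matrices -> per-environment REML -> cross-environment GxE ->
GWAS -> study report.

Every stage persists its artifacts under the output directory so each can be
re-run standalone; all randomness flows from the single seed in the config.
The report is written both as TSV tables and as one machine-readable JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas as gwas_mod
from . import qc as qc_mod
from .parentage import assign_parents, assignments_frame, family_summary
from .pedigree import Pedigree
from .plinkio import SnpPanel, read_panel
from .relmat import a_matrix, grm_vanraden, h_matrix, matrix_element_correlations
from .synth import SimConfig, condition_factor, simulate_all
from .varcomp import (
    ModelSpec,
    derive_params,
    genetic_correlations,
    gxe_fit,
    prune_nested_factors,
    reml_fit,
)

log = logging.getLogger("smoltgxe")


def rate(events: int, population: int) -> float:
    """Percentage 100*events/population, reported to 2 decimals."""
    if population <= 0:
        raise ZeroDivisionError("population must be positive")
    return round(100.0 * events / population, 2)


def descriptive_stats(pheno: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Mean, SE, SD and raw CV per trait x environment x sex.

    The condition factor is derived as 100*W/L^3 when absent.
    """
    if pheno.empty:
        raise ValueError("empty phenotype table")
    df = pheno.copy()
    if "K" not in df.columns and {"WBW", "length"} <= set(df.columns):
        df["K"] = condition_factor(df["WBW"], df["length"])
    if traits is None:
        traits = [c for c in df.columns if c not in ("id", "env", "tank", "sex")]
    rows = []
    for (env, sex), grp in df.groupby(["env", "sex"]):
        for t in traits:
            x = grp[t].dropna()
            sd = float(x.std(ddof=1)) if len(x) > 1 else float("nan")
            m = float(x.mean())
            rows.append(
                {
                    "env": env,
                    "sex": sex,
                    "trait": t,
                    "n": len(x),
                    "mean": m,
                    "se": sd / np.sqrt(len(x)) if len(x) > 1 else float("nan"),
                    "sd": sd,
                    "cv_raw_pct": 100 * sd / m if m != 0 and len(x) > 1 else float("nan"),
                }
            )
    for env, grp in df.groupby("env"):
        for t in traits:
            x = grp[t].dropna()
            sd = float(x.std(ddof=1)) if len(x) > 1 else float("nan")
            m = float(x.mean())
            rows.append(
                {
                    "env": env,
                    "sex": "all",
                    "trait": t,
                    "n": len(x),
                    "mean": m,
                    "se": sd / np.sqrt(len(x)) if len(x) > 1 else float("nan"),
                    "sd": sd,
                    "cv_raw_pct": 100 * sd / m if m != 0 and len(x) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """One config drives the whole run. ``mode`` is 'simulate' or 'ingest'."""

    mode: str = "simulate"
    out_dir: str = "results/run"
    seed: int = 0
    sim: SimConfig | None = None
    # ingest-mode paths
    founder_prefix: str | None = None
    offspring_prefix: str | None = None
    pedigree_path: str | None = None
    pheno_path: str | None = None
    # analysis options
    qc_mind: float = 0.10
    qc_geno: float = 0.10
    qc_hwe: float = 1e-6
    qc_maf: float = 0.005
    oh_threshold: float = 0.01
    relationship: str = "G"  # A, G or H for the REML stages
    traits: tuple = ("WBW", "length", "K")
    gxe_traits: tuple = ("WBW",)
    run_gwas: bool = True
    gwas_traits: tuple = ("WBW",)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate":
            if self.sim is None:
                self.sim = SimConfig(seed=self.seed)
        else:
            for p in (self.offspring_prefix, self.pedigree_path, self.pheno_path):
                if p is None or not Path(str(p) + "").parent.exists():
                    raise ValueError("ingest mode requires existing input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            for key in ("G_env1", "G_env2", "R_env1", "R_env2"):
                if key in sim:
                    sim[key] = np.asarray(sim[key], dtype=float)
            for key in (
                "trait_names", "trait_means_env1", "trait_means_env2",
                "sex_effect", "tank_sd_env1", "tank_sd_env2", "env_names",
                "r_g_across_env", "maf_distribution",
            ):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            cfg.sim = SimConfig(**sim)
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def run(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable study report."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "mode": config.mode, "stages": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %-12s %6.1fs", name, time.time() - t0)

    # ---- inputs ----------------------------------------------------------
    if config.mode == "simulate":
        ped, fpanel, opanel, pheno, truth = simulate_all(config.sim)
        fpanel.write(str(out / "founders"), "bed")
        opanel.write(str(out / "offspring"), "bed")
        ped.write_tsv(out / "pedigree.tsv")
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "metadata.json").write_text(
            json.dumps({"seed": config.sim.seed, "mode": "simulate"}, indent=1)
        )
    else:
        fpanel = read_panel(config.founder_prefix) if config.founder_prefix else None
        opanel = read_panel(config.offspring_prefix)
        ped = Pedigree.read_tsv(config.pedigree_path)
        pheno = pd.read_csv(config.pheno_path, sep="\t")
        pheno["id"] = pheno["id"].astype(str)
    stage("inputs")

    # ---- QC --------------------------------------------------------------
    opanel_qc, rep_o = qc_mod.qc_panel(
        opanel, config.qc_mind, config.qc_geno, config.qc_hwe, config.qc_maf
    )
    report["stages"]["qc_offspring"] = {
        k: v for k, v in asdict(rep_o).items() if k != "removed_individual_ids"
    }
    if fpanel is not None:
        fpanel_qc, rep_f = qc_mod.qc_panel(
            fpanel, config.qc_mind, config.qc_geno, config.qc_hwe, config.qc_maf
        )
        report["stages"]["qc_founders"] = {
            k: v for k, v in asdict(rep_f).items() if k != "removed_individual_ids"
        }
        fpanel_qc, opanel_qc = qc_mod.intersect_panels(fpanel_qc, opanel_qc)
        report["stages"]["common_snps"] = opanel_qc.n_markers
    rep_o.to_tsv(out / "qc_report.tsv")
    stage("qc")

    # ---- parentage (only when founder genotypes are available) -----------
    if fpanel is not None:
        ftab = ped.table[ped.table["id"].isin(set(fpanel_qc.ids))]
        sire_ids = ftab.loc[ftab["sex"] == "M", "id"].tolist()
        dam_ids = ftab.loc[ftab["sex"] != "M", "id"].tolist()
        sires = fpanel_qc.subset(individuals=sire_ids)
        dams = fpanel_qc.subset(individuals=dam_ids)
        off_tab = ped.table[ped.table["id"].isin(set(opanel_qc.ids))]
        known = set(zip(off_tab["sire"], off_tab["dam"]))
        assignments = assign_parents(
            opanel_qc, sires, dams, known, config.oh_threshold
        )
        adf = assignments_frame(assignments)
        adf.to_csv(out / "parent_assignments.csv", index=False)
        fam_sizes, fam_stats = family_summary(assignments, pheno)
        fam_sizes.to_csv(out / "family_sizes.tsv", sep="\t", index=False)
        report["stages"]["parentage"] = {
            "n_oh_confirmed": int((adf["status"] == "oh_confirmed").sum()),
            "n_likelihood": int((adf["status"] == "likelihood_assigned").sum()),
            "n_unassigned": int((adf["status"] == "unassigned").sum()),
            **{k: v for k, v in fam_stats.items()},
        }
        stage("parentage")

    # ---- descriptive statistics -----------------------------------------
    desc = descriptive_stats(pheno)
    desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)
    report["stages"]["descriptives"] = desc
    stage("descriptives")

    # ---- relationship matrices ------------------------------------------
    pheno_ids = pheno["id"].astype(str).tolist()
    A = a_matrix(ped, subjects=None)
    G = grm_vanraden(opanel_qc)
    genotyped_pheno = [i for i in pheno_ids if i in set(G.ids)]
    report["stages"]["a_g_correlations"] = matrix_element_correlations(A, G)
    if config.relationship == "A":
        K = A.submatrix(pheno_ids)
    elif config.relationship == "G":
        K = G
    else:
        K = h_matrix(A, G, list(G.ids)).submatrix(pheno_ids)
    stage("relmat")

    # ---- per-environment univariate REML (Table-1 layout) ----------------
    envs = sorted(pheno["env"].astype(str).unique())
    table1 = []
    for env in envs:
        sub = pheno[pheno["env"].astype(str) == env]
        if config.relationship == "G":
            sub = sub[sub["id"].astype(str).isin(set(K.ids))]
        fixed = prune_nested_factors(sub, ["sex", "tank"])
        for t in config.traits:
            spec = ModelSpec(traits=[t], fixed=fixed)
            fit = reml_fit(sub, K, spec)
            d = derive_params(fit, {t: float(sub[t].mean())}).iloc[0].to_dict()
            raw_sd = float(sub[t].std(ddof=1))
            d["CV_raw_pct"] = 100 * raw_sd / float(sub[t].mean())
            d["env"] = env
            d["converged"] = fit.converged
            table1.append(d)
    tab1 = pd.DataFrame(table1)
    tab1.to_csv(out / "table1_variance_components.tsv", sep="\t", index=False)
    report["stages"]["variance_components"] = tab1
    stage("reml")

    # ---- within-environment trait correlations (Table-2 layout) ----------
    table2 = []
    for env in envs:
        sub = pheno[pheno["env"].astype(str) == env]
        if config.relationship == "G":
            sub = sub[sub["id"].astype(str).isin(set(K.ids))]
        fixed = prune_nested_factors(sub, ["sex", "tank"])
        for i in range(len(config.traits)):
            for j in range(i + 1, len(config.traits)):
                pair = [config.traits[i], config.traits[j]]
                spec = ModelSpec(traits=pair, fixed=fixed)
                fit = reml_fit(sub, K, spec)
                row = genetic_correlations(fit).iloc[0].to_dict()
                row["env"] = env
                row["converged"] = fit.converged
                table2.append(row)
    tab2 = pd.DataFrame(table2)
    tab2.to_csv(out / "table2_correlations.tsv", sep="\t", index=False)
    report["stages"]["trait_correlations"] = tab2
    stage("multivariate")

    # ---- cross-environment GxE -------------------------------------------
    gxe_rows = []
    for t in config.gxe_traits:
        fit = gxe_fit(pheno if config.relationship != "G" else pheno[
            pheno["id"].astype(str).isin(set(K.ids))
        ], K, t)
        row = genetic_correlations(fit).iloc[0].to_dict()
        row["trait"] = t
        row["converged"] = fit.converged
        gxe_rows.append(row)
    gxe_tab = pd.DataFrame(gxe_rows)
    gxe_tab.to_csv(out / "gxe_genetic_correlations.tsv", sep="\t", index=False)
    report["stages"]["gxe"] = gxe_tab
    stage("gxe")

    # ---- GWAS -------------------------------------------------------------
    if config.run_gwas:
        n_snps = opanel_qc.n_markers
        n_chrom = opanel_qc.markers["chrom"].astype(str).nunique()
        thr = gwas_mod.bonferroni_thresholds(n_snps, n_chrom)
        report["stages"]["gwas_thresholds"] = {
            "genome": thr[0], "chromosome": thr[1],
            "n_snps": n_snps, "n_chromosomes": n_chrom,
        }
        counts_tab = []
        loco = gwas_mod.loco_grm_set(opanel_qc)
        for env in envs:
            sub = pheno[pheno["env"].astype(str) == env]
            sub = sub[sub["id"].astype(str).isin(set(opanel_qc.ids))]
            for t in config.gwas_traits:
                res = gwas_mod.mlma(sub, opanel_qc, t, loco_grms=loco)
                res.to_csv(out / f"gwas_{t}_{env}.tsv", sep="\t", index=False)
                counts, _ = gwas_mod.significant_snps(res, *thr)
                counts_tab.append({"env": env, "trait": t, **counts})
                gwas_mod.manhattan_plot(res, thr, out / f"gwas_{t}_{env}.png")
        tab3 = pd.DataFrame(counts_tab)
        tab3.to_csv(out / "table3_significant_snps.tsv", sep="\t", index=False)
        report["stages"]["gwas_counts"] = tab3
        stage("gwas")

    report["elapsed_s"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(
        json.dumps(_jsonable({k: v for k, v in report.items() if k != "elapsed_s"}),
                   indent=1, sort_keys=True)
    )
    stage("done")
    return report
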