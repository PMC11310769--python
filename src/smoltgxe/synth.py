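"""Synthetic nucleus-breeding-population generator with known ground truth.

Emulates a salmon nucleus programme: ~72 sires and ~139 dams under a mostly
1-sire:2-dam hierarchical mating design producing ~140 full-sib families,
biallelic SNPs on 29 chromosomes, and growth traits (whole-body weight in g,
fork length in cm; Fulton's condition factor K = 100*W/L^3 derived) expressed
in two rearing environments with environment-specific genetic and residual
(co)variances and a controllable cross-environment genetic correlation.

The cross-environment correlation acts at the SNP-effect level: each marker
gets one effect per (trait, environment) cell drawn from a joint normal whose
correlation combines the within-environment trait correlations with the
per-trait cross-environment correlation, so genotype -> phenotype causality
is preserved for association testing. Effects are rescaled so the genic
variance sum(2*p0*q0*beta^2) over founder allele frequencies p0 matches the
configured genetic variance exactly. Loci are unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree
from .plinkio import MISSING, SnpPanel

ENV1, ENV2 = "RAS", "loch"


def condition_factor(weight_g, length_cm):
    """Fulton's condition factor, 100 * W / L^3 (W in g, L in cm)."""
    return 100.0 * np.asarray(weight_g) / np.asarray(length_cm) ** 3


class ConfigError(ValueError):
    pass


def _check_psd(M, name):
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T):
        raise ConfigError(f"{name} not symmetric")
    if np.linalg.eigvalsh(M).min() < -1e-10:
        raise ConfigError(f"{name} not positive semi-definite")
    return M


@dataclass
class SimConfig:
    """Study-design parameters. Defaults are the study conditions:
    72 sires x 139 dams (1:2 matings), 14 offspring per family split ~7/7
    across two environments, 3,000 SNPs on 29 chromosomes, and Table-1-scale
    trait (co)variances with cross-environment genetic correlations
    (0.62 weight, 0.78 length)."""

    n_sires: int = 72
    n_dams: int = 139
    dams_per_sire: int = 2
    offspring_per_family: int | Callable = 14
    n_snps: int = 3000
    n_chromosomes: int = 29
    maf_distribution: float | tuple | Callable = (0.05, 0.5)
    trait_names: tuple = ("WBW", "length")
    trait_means_env1: tuple = (88.03, 19.05)
    trait_means_env2: tuple = (121.87, 21.35)
    G_env1: np.ndarray = field(
        default_factory=lambda: np.array([[127.10, 7.943], [7.943, 0.55]])
    )
    G_env2: np.ndarray = field(
        default_factory=lambda: np.array([[129.58, 7.017], [7.017, 0.43]])
    )
    r_g_across_env: float | tuple = (0.62, 0.78)
    R_env1: np.ndarray = field(
        default_factory=lambda: np.array([[175.08, 11.33], [11.33, 0.83]])
    )
    R_env2: np.ndarray = field(
        default_factory=lambda: np.array([[591.94, 34.17], [34.17, 2.33]])
    )
    sex_effect: tuple = (-6.57, -0.404)  # male minus female
    n_tanks_per_env: int = 6
    tank_sd_env1: tuple = (3.0, 0.10)
    tank_sd_env2: tuple = (0.0, 0.0)
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    cull_fraction: float = 0.0
    causal_chromosomes: tuple | None = None  # None: every marker is causal
    env_names: tuple = (ENV1, ENV2)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_sires", "n_dams", "dams_per_sire", "n_snps", "n_chromosomes"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.n_sires * self.dams_per_sire < self.n_dams:
            raise ConfigError(
                "mating design inconsistent: n_sires * dams_per_sire < n_dams"
            )
        T = len(self.trait_names)
        self.G_env1 = _check_psd(self.G_env1, "G_env1")
        self.G_env2 = _check_psd(self.G_env2, "G_env2")
        self.R_env1 = _check_psd(self.R_env1, "R_env1")
        self.R_env2 = _check_psd(self.R_env2, "R_env2")
        for M, name in (
            (self.G_env1, "G_env1"), (self.G_env2, "G_env2"),
            (self.R_env1, "R_env1"), (self.R_env2, "R_env2"),
        ):
            if M.shape != (T, T):
                raise ConfigError(f"{name} shape {M.shape} != ({T}, {T})")
        rg = np.atleast_1d(np.asarray(self.r_g_across_env, dtype=float))
        if rg.size == 1:
            rg = np.repeat(rg, T)
        if rg.size != T or np.any(np.abs(rg) > 1):
            raise ConfigError("r_g_across_env must be per-trait values in [-1, 1]")
        self._rg = rg
        for name in ("genotyping_error_rate", "missing_rate", "cull_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name}={v} outside [0, 1)")
        if isinstance(self.maf_distribution, tuple):
            lo, hi = self.maf_distribution
            if not (0 < lo <= hi <= 0.5):
                raise ConfigError("maf_distribution support must lie in (0, 0.5]")
        elif isinstance(self.maf_distribution, (int, float)):
            if not 0 < self.maf_distribution <= 0.5:
                raise ConfigError("maf_distribution support must lie in (0, 0.5]")

    def draw_mafs(self, rng: np.random.Generator) -> np.ndarray:
        d = self.maf_distribution
        if callable(d):
            p = np.asarray(d(rng, self.n_snps), dtype=float)
        elif isinstance(d, tuple):
            p = rng.uniform(d[0], d[1], self.n_snps)
        else:
            p = np.full(self.n_snps, float(d))
        if np.any((p <= 0) | (p > 0.5)):
            raise ConfigError("maf draws outside (0, 0.5]")
        return p


def _marker_map(config: SimConfig) -> pd.DataFrame:
    m, c = config.n_snps, config.n_chromosomes
    per = np.full(c, m // c)
    per[: m % c] += 1
    chrom = np.repeat(np.arange(1, c + 1), per)
    pos = np.concatenate([np.arange(1, k + 1) * 10_000 for k in per])
    return pd.DataFrame(
        {
            "snp": [f"snp{j + 1}" for j in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "a1": "A",
            "a2": "B",
        }
    )


def simulate_founders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Pedigree, SnpPanel]:
    """Unrelated founders with genotypes binomial(2, p), p ~ maf_distribution."""
    rng = rng or np.random.default_rng(config.seed)
    sires = [f"S{i + 1:04d}" for i in range(config.n_sires)]
    dams = [f"D{i + 1:04d}" for i in range(config.n_dams)]
    ped = Pedigree(
        pd.DataFrame(
            {
                "id": sires + dams,
                "sire": UNKNOWN,
                "dam": UNKNOWN,
                "sex": ["M"] * len(sires) + ["F"] * len(dams),
            }
        )
    )
    p = config.draw_mafs(rng)
    geno = rng.binomial(2, p, size=(len(sires) + len(dams), config.n_snps)).astype(
        np.int8
    )
    sex = {i: ("1" if i.startswith("S") else "2") for i in ped.ids}
    return ped, SnpPanel(ped.ids, _marker_map(config), geno, sex)


def _transmit(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per locus per row: hom transmits its allele, het a fair coin."""
    het = parent_geno == 1
    gam = (parent_geno == 2).astype(np.int8)
    gam[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return gam


def mate_and_drop(
    founders: Pedigree,
    founder_panel: SnpPanel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Pedigree, SnpPanel]:
    """Hierarchical matings plus Mendelian gene dropping.

    Dam ``j`` mates sire ``j // dams_per_sire``; each dam founds one full-sib
    family. The returned panel holds the observed offspring genotypes (after
    genotyping error and missingness); the pre-error dosages are kept on the
    panel as ``true_geno`` for ground-truth phenotype construction.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    ftab = founders.table
    sires = ftab.loc[ftab["sex"] == "M", "id"].tolist()
    dams = ftab.loc[ftab["sex"] != "M", "id"].tolist()
    pos = {ind: i for i, ind in enumerate(founder_panel.ids)}
    fam_sire = [sires[j // config.dams_per_sire] for j in range(len(dams))]

    rows, off_ids, sire_rows, dam_rows = [], [], [], []
    counter = 1
    for j, dam in enumerate(dams):
        size = (
            config.offspring_per_family(rng)
            if callable(config.offspring_per_family)
            else config.offspring_per_family
        )
        for _ in range(int(size)):
            oid = f"O{counter:05d}"
            counter += 1
            off_ids.append(oid)
            rows.append((oid, fam_sire[j], dam))
            sire_rows.append(pos[fam_sire[j]])
            dam_rows.append(pos[dam])
    sex = rng.choice(["M", "F"], size=len(off_ids))
    off_tab = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    off_tab["sex"] = sex

    gs = founder_panel.geno[sire_rows]
    gd = founder_panel.geno[dam_rows]
    true_geno = (_transmit(gs, rng) + _transmit(gd, rng)).astype(np.int8)

    obs = true_geno.copy()
    if config.genotyping_error_rate > 0:
        err = rng.random(obs.shape) < config.genotyping_error_rate
        flip_dir = rng.integers(0, 2, size=obs.shape, dtype=np.int8)
        new = obs.copy()
        new[err & (obs == 0)] = 1
        new[err & (obs == 2)] = 1
        het_err = err & (obs == 1)
        new[het_err] = (2 * flip_dir[het_err]).astype(np.int8)
        obs = new
    if config.missing_rate > 0:
        obs[rng.random(obs.shape) < config.missing_rate] = MISSING

    panel = SnpPanel(
        off_ids,
        founder_panel.markers.copy(),
        obs,
        {o: ("1" if s == "M" else "2") for o, s in zip(off_ids, sex)},
    )
    panel.true_geno = true_geno
    return founders.extended_with(off_tab), panel


def _effect_correlation(config: SimConfig) -> np.ndarray:
    """Correlation of per-SNP effects over (trait, env) cells, trait-major
    within environment. Projected to the nearest correlation matrix if the
    assembled one is indefinite."""
    T = len(config.trait_names)
    rg = config._rg

    def corr(M):
        d = np.sqrt(np.diag(M))
        with np.errstate(invalid="ignore", divide="ignore"):
            C = M / np.outer(d, d)
        C[~np.isfinite(C)] = 0.0
        np.fill_diagonal(C, 1.0)
        return C

    C1, C2 = corr(config.G_env1), corr(config.G_env2)
    n = 2 * T
    C = np.eye(n)
    C[:T, :T] = C1
    C[T:, T:] = C2
    for t in range(T):
        for s in range(T):
            if t == s:
                v = rg[t]
            else:
                v = 0.5 * (C1[t, s] + C2[t, s]) * np.sqrt(abs(rg[t] * rg[s]))
            C[t, T + s] = v
            C[T + s, t] = v
    C = (C + C.T) / 2
    w, U = np.linalg.eigh(C)
    if w.min() < -1e-10:  # indefinite: project to the nearest PSD correlation
        w = np.clip(w, 0.0, None)
        C = U @ np.diag(w) @ U.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    return C


def simulate_phenotypes(
    pedigree: Pedigree,
    panel: SnpPanel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes in two environments plus the ground-truth records.

    Breeding values are centered-dosage times SNP effects (true, pre-error
    dosages); phenotype = intercept + sex effect + tank effect + breeding
    value in the environment of residence + residual from R_env. Individuals
    are split between environments stratified by family and sex; tanks are
    single-sex within environment. Condition factor K is derived from the
    simulated weight and length.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    T = len(config.trait_names)
    envs = list(config.env_names)

    # effects are centered on founder allele frequencies when available
    # (attached by simulate_all); otherwise on the offspring panel frequencies
    p0 = getattr(panel, "founder_freq", None)
    if p0 is None:
        p0 = (
            panel.true_geno.mean(axis=0) / 2.0
            if hasattr(panel, "true_geno")
            else panel.allele_freq()
        )
    p0 = np.clip(np.asarray(p0, dtype=float), 1e-6, 1 - 1e-6)

    C = _effect_correlation(config)
    # symmetric square root (handles the singular case r_g = +-1 exactly)
    w, U = np.linalg.eigh(C)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    beta = rng.standard_normal((config.n_snps, 2 * T)) @ L.T
    if config.causal_chromosomes is not None:
        causal = (
            panel.markers["chrom"]
            .astype(str)
            .isin({str(c) for c in config.causal_chromosomes})
            .to_numpy()
        )
        if not causal.any():
            raise ConfigError("causal_chromosomes matches no markers")
        beta[~causal] = 0.0
    het = 2 * p0 * (1 - p0)
    G_diag = np.concatenate([np.diag(config.G_env1), np.diag(config.G_env2)])
    for c in range(2 * T):
        genic = float(het @ beta[:, c] ** 2)
        beta[:, c] *= np.sqrt(G_diag[c] / genic) if genic > 0 else 0.0

    dosage = getattr(panel, "true_geno", None)
    if dosage is None:
        d = panel.geno.astype(float)
        d[panel.geno == MISSING] = np.nan
        dosage = np.where(np.isnan(d), 2 * p0, d)
    Zc = dosage.astype(float) - 2 * p0
    BV = Zc @ beta  # n_off x (2T), trait-major within env

    off = pedigree.table[pedigree.table["id"].isin(set(panel.ids))].copy()
    off = off.set_index("id").loc[panel.ids].reset_index()
    off["family"] = off["sire"] + "x" + off["dam"]

    # stratified environment split within family x sex
    env_assign = pd.Series(index=off["id"], dtype=object)
    for _, grp in off.groupby(["family", "sex"]):
        k = len(grp)
        half = k // 2
        lab = np.array([envs[0]] * half + [envs[1]] * (k - half), dtype=object)
        if k % 2:
            lab[-1] = envs[int(rng.integers(0, 2))]
        rng.shuffle(lab)
        env_assign.loc[grp["id"].tolist()] = lab
    off["env"] = env_assign.loc[off["id"]].to_numpy()

    # single-sex tanks: half the tanks per environment for each sex
    nt = config.n_tanks_per_env
    tank_names = {
        e: {
            "M": [f"{e}_T{k + 1}" for k in range(nt // 2)],
            "F": [f"{e}_T{k + 1}" for k in range(nt // 2, nt)],
        }
        for e in envs
    }
    if nt < 2:
        tank_names = {e: {"M": [f"{e}_T1"], "F": [f"{e}_T1"]} for e in envs}
    off["tank"] = [
        rng.choice(tank_names[e][s]) for e, s in zip(off["env"], off["sex"])
    ]
    tank_sd = {envs[0]: np.asarray(config.tank_sd_env1, dtype=float),
               envs[1]: np.asarray(config.tank_sd_env2, dtype=float)}
    tank_fx = {}
    for e in envs:
        for tk in set(tank_names[e]["M"] + tank_names[e]["F"]):
            tank_fx[tk] = rng.standard_normal(T) * tank_sd[e]

    means = {envs[0]: np.asarray(config.trait_means_env1, dtype=float),
             envs[1]: np.asarray(config.trait_means_env2, dtype=float)}
    R = {envs[0]: config.R_env1, envs[1]: config.R_env2}
    sex_fx = np.asarray(config.sex_effect, dtype=float)

    Y = np.empty((len(off), T))
    for e_i, e in enumerate(envs):
        mask = (off["env"] == e).to_numpy()
        ne = int(mask.sum())
        if ne == 0:
            continue
        resid = rng.multivariate_normal(np.zeros(T), R[e], size=ne, method="cholesky") \
            if np.any(R[e]) else np.zeros((ne, T))
        bv = BV[mask][:, e_i * T : (e_i + 1) * T]
        tanks = np.stack([tank_fx[tk] for tk in off.loc[mask, "tank"]])
        is_male = (off.loc[mask, "sex"] == "M").to_numpy()[:, None]
        Y[mask] = means[e] + is_male * sex_fx + tanks + bv + resid

    pheno = off[["id", "env", "tank", "sex"]].copy()
    for t_i, t in enumerate(config.trait_names):
        pheno[t] = Y[:, t_i]
    if set(("WBW", "length")) <= set(config.trait_names):
        pheno["K"] = condition_factor(pheno["WBW"], pheno["length"])

    truth = off[["id", "family", "env", "sex"]].copy()
    for e_i, e in enumerate(envs):
        for t_i, t in enumerate(config.trait_names):
            truth[f"bv_{t}@{e}"] = BV[:, e_i * T + t_i]
    # ground-truth generative quantities for recovery/property checks
    truth.attrs["snp_effects"] = beta
    truth.attrs["p0"] = p0
    truth.attrs["effect_columns"] = [
        f"{t}@{e}" for e in envs for t in config.trait_names
    ]
    if config.cull_fraction > 0:
        pheno, _removed = apply_cull(pheno, config.cull_fraction, config.trait_names[0])
    return pheno, truth


def apply_cull(
    pheno: pd.DataFrame, fraction: float, trait: str
) -> tuple[pd.DataFrame, list[str]]:
    """Remove the lowest ``fraction`` quantile on ``trait``."""
    if not 0 <= fraction < 1:
        raise ConfigError(f"cull fraction {fraction} outside [0, 1)")
    if fraction == 0:
        return pheno.copy(), []
    n_remove = int(np.floor(fraction * len(pheno)))
    if n_remove == 0:
        return pheno.copy(), []
    order = pheno[trait].to_numpy().argsort()
    removed_idx = order[:n_remove]
    removed = pheno["id"].iloc[removed_idx].tolist()
    return pheno.drop(pheno.index[removed_idx]).reset_index(drop=True), removed


def simulate_all(
    config: SimConfig,
) -> tuple[Pedigree, SnpPanel, SnpPanel, pd.DataFrame, pd.DataFrame]:
    """Full simulation: (pedigree, founder panel, offspring panel, phenotypes,
    truth records). All randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    founders, fpanel = simulate_founders(config, rng)
    ped, opanel = mate_and_drop(founders, fpanel, config, rng)
    opanel.founder_freq = fpanel.geno.mean(axis=0) / 2.0
    pheno, truth = simulate_phenotypes(ped, opanel, config, rng)
    return ped, fpanel, opanel, pheno, truth
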