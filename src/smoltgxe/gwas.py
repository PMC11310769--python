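"""Mixed-linear-model association with leave-one-chromosome-out correction.

For each chromosome, variance components are re-estimated by REML under a
genomic relationship matrix built from all OTHER chromosomes; each marker on
the chromosome is then added as a fixed covariate and tested with the
generalized-least-squares Wald statistic (effect^2 / SE^2 against chi-square,
1 df), holding the variance components fixed within the chromosome.

Significance lines follow Bonferroni control at two levels:
genome-wide -log10(0.05 / n_snps) and chromosome-wide
-log10(0.05 / (n_snps / n_chromosomes)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .plinkio import MISSING, SnpPanel
from .relmat import RelMatrix
from .varcomp import ModelSpec, reml_fit


def bonferroni_thresholds(n_snps: int, n_chromosomes: int) -> tuple[float, float]:
    """(genome, chromosome) significance lines on the -log10(p) scale."""
    if n_snps < 1 or n_chromosomes < 1:
        raise ValueError("n_snps and n_chromosomes must be >= 1")
    genome = -np.log10(0.05 / n_snps)
    chrom = -np.log10(0.05 / (n_snps / n_chromosomes))
    return float(genome), float(chrom)


def loco_grm_set(panel: SnpPanel) -> dict[str, RelMatrix]:
    """VanRaden GRM per chromosome, built from all markers NOT on it.

    Computed as the full-panel cross-product minus each chromosome's
    contribution, with the 2*sum(p(1-p)) denominator restricted to the
    retained markers.
    """
    chroms = panel.markers["chrom"].astype(str)
    uniq = list(dict.fromkeys(chroms))
    if len(uniq) < 2:
        raise ValueError("LOCO needs at least 2 chromosomes")
    p = panel.allele_freq()
    het = 2 * p * (1 - p)
    if np.any(np.isnan(p)) or np.any(het <= 0):
        raise ValueError("monomorphic or all-missing markers; run QC first")
    Z = panel.geno.astype(float)
    Z[panel.geno == MISSING] = np.nan
    Z = np.where(np.isnan(Z), 2 * p, Z) - 2 * p
    S_full = Z @ Z.T
    out = {}
    for c in uniq:
        cols = np.flatnonzero((chroms == c).to_numpy())
        Zc = Z[:, cols]
        S_c = Zc @ Zc.T
        denom = het.sum() - het[cols].sum()
        out[c] = RelMatrix(list(panel.ids), (S_full - S_c) / denom, "G_loco")
    return out


def mlma(
    pheno: pd.DataFrame,
    panel: SnpPanel,
    trait: str,
    fixed: list[str] = ("sex", "tank"),
    loco_grms: dict[str, RelMatrix] | None = None,
    genetic_id: str = "id",
    reestimate_per_chromosome: bool = True,
    fixed_vc: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-marker association scan for one trait.

    Returns a frame with marker, chromosome, position, allele effect, SE,
    chi-square, p and -log10 p; markers with zero dosage variance after
    mean imputation are flagged ``untestable`` with p = NaN. Markers on a
    chromosome whose REML fit did not converge are flagged ``no_vc``.
    """
    from .varcomp import prune_nested_factors

    fixed = prune_nested_factors(pheno, [f for f in fixed if f in pheno.columns])
    if loco_grms is None:
        loco_grms = loco_grm_set(panel)
    from .varcomp import build_design

    sub = pheno.dropna(subset=[trait]).copy()
    sub[genetic_id] = sub[genetic_id].astype(str)
    sub = sub[sub[genetic_id].isin(set(panel.ids))]
    gpanel = panel.subset(individuals=sub[genetic_id].tolist())

    p = panel.allele_freq()
    chroms = panel.markers["chrom"].astype(str)
    spec = ModelSpec(traits=[trait], fixed=fixed, genetic_id=genetic_id)

    rows = []
    vc_global = None
    for c, K in loco_grms.items():
        cols = np.flatnonzero((chroms == c).to_numpy())
        if len(cols) == 0:
            continue
        if fixed_vc is not None:
            vg, vr = float(fixed_vc[0]), float(fixed_vc[1])
            converged = True
        else:
            if reestimate_per_chromosome or vc_global is None:
                fit = reml_fit(sub, K, spec)
                vc_global = fit
            else:
                fit = vc_global
            vg = float(fit.G.iloc[0, 0])
            vr = float(fit.R.iloc[0, 0])
            converged = fit.converged
        d = build_design(sub, spec, K.ids)[0]
        y, X, idx = d["y"], d["X"], d["k_idx"]
        V = vg * K.values[np.ix_(idx, idx)] + vr * np.eye(len(y))
        cho = linalg.cho_factor(V, check_finite=False)
        VX = linalg.cho_solve(cho, X, check_finite=False)
        cxx = linalg.cho_factor(X.T @ VX, check_finite=False)
        Vy = linalg.cho_solve(cho, y, check_finite=False)
        Py = Vy - VX @ linalg.cho_solve(cxx, X.T @ Vy, check_finite=False)

        G = gpanel.geno[:, cols].astype(float)
        miss = gpanel.geno[:, cols] == MISSING
        G[miss] = np.nan
        G = np.where(np.isnan(G), 2 * p[cols], G)
        PG = linalg.cho_solve(cho, G, check_finite=False)
        PG -= VX @ linalg.cho_solve(cxx, VX.T @ G, check_finite=False)
        num = G.T @ Py
        den = np.einsum("ij,ij->j", G, PG)
        testable = den > 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = np.where(testable, num / den, np.nan)
            se = np.where(testable, np.sqrt(1.0 / den), np.nan)
            chi2 = np.where(testable, num**2 / den, np.nan)
        pval = np.where(testable, stats.chi2.sf(chi2, df=1), np.nan)
        flag = np.where(testable, "ok" if converged else "no_vc", "untestable")
        mk = panel.markers.iloc[cols]
        rows.append(
            pd.DataFrame(
                {
                    "snp": mk["snp"].to_numpy(),
                    "chrom": mk["chrom"].astype(str).to_numpy(),
                    "pos": mk["pos"].to_numpy(),
                    "effect": eff,
                    "se": se,
                    "chi2": chi2,
                    "p": pval,
                    "flag": flag,
                }
            )
        )
    res = pd.concat(rows, ignore_index=True)
    with np.errstate(divide="ignore"):
        res["neglog10p"] = -np.log10(res["p"])
    return res


def significant_snps(
    result: pd.DataFrame, genome_threshold: float, chrom_threshold: float
) -> tuple[dict[str, int], pd.DataFrame]:
    """Counts and table of markers exceeding each -log10 threshold."""
    ok = result.dropna(subset=["neglog10p"])
    at_genome = ok[ok["neglog10p"] >= genome_threshold]
    at_chrom = ok[ok["neglog10p"] >= chrom_threshold]
    counts = {"genome": int(len(at_genome)), "chromosome": int(len(at_chrom))}
    tab = at_chrom.copy()
    tab["genome_level"] = tab["neglog10p"] >= genome_threshold
    return counts, tab.sort_values("neglog10p", ascending=False)


def manhattan_plot(result: pd.DataFrame, thresholds: tuple[float, float], path):
    """Simple Manhattan plot with dashed genome and chromosome lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = result.dropna(subset=["neglog10p"]).copy()
    chrom_order = list(dict.fromkeys(res["chrom"]))
    offset = 0
    xs, colors = [], []
    ticks = []
    for i, c in enumerate(chrom_order):
        sub = res[res["chrom"] == c]
        xs.append(offset + sub["pos"].to_numpy().astype(float))
        colors.append(np.full(len(sub), i % 2))
        ticks.append(offset + sub["pos"].max() / 2)
        offset += sub["pos"].max() + 1
    x = np.concatenate(xs)
    col = np.concatenate(colors)
    fig, ax = plt.subplots(figsize=(9, 3))
    for v, cname in ((0, "#1f77b4"), (1, "#7fb3d8")):
        m = col == v
        ax.scatter(x[m], res["neglog10p"].to_numpy()[m], s=4, color=cname)
    ax.axhline(thresholds[0], ls="--", color="red", lw=0.8)
    ax.axhline(thresholds[1], ls="--", color="gray", lw=0.8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(chrom_order, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
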