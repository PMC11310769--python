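"""Genotype quality control.

Filter chain (PLINK-like order): duplicate markers -> individual missingness
-> SNP missingness -> Hardy-Weinberg exact test -> minor allele frequency.
The HWE test is the exact conditional test (enumeration over heterozygote
counts given the minor-allele count), which stays calibrated at low MAF where
the chi-square approximation fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .plinkio import MISSING, SnpPanel


@dataclass
class QcReport:
    """Bookkeeping of what each filter removed."""

    n_individuals_before: int = 0
    n_markers_before: int = 0
    removed_duplicates: int = 0
    removed_individuals_missing: int = 0
    removed_snp_missing: int = 0
    removed_hwe: int = 0
    removed_maf: int = 0
    n_individuals_after: int = 0
    n_markers_after: int = 0
    removed_individual_ids: list = field(default_factory=list)

    def consistent(self) -> bool:
        ok_ind = (
            self.n_individuals_before - self.removed_individuals_missing
            == self.n_individuals_after
        )
        ok_mark = (
            self.n_markers_before
            - self.removed_duplicates
            - self.removed_snp_missing
            - self.removed_hwe
            - self.removed_maf
            == self.n_markers_after
        )
        return ok_ind and ok_mark

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [(k, v) for k, v in self.__dict__.items() if k != "removed_individual_ids"]
        pd.DataFrame(rows, columns=["filter", "count"]).to_csv(
            path, sep="\t", index=False
        )


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed
    minor-allele count, the probabilities no larger than that of the
    observed configuration.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_minor = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    # P(het | n, n_minor) ∝ n! / (hom_min! het! hom_maj!) * 2^het
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_min + 1)
        - gammaln(hets + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[np.searchsorted(hets, n_het)]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def hwe_pvalues(panel: SnpPanel) -> np.ndarray:
    g = panel.geno
    n_het = (g == 1).sum(axis=0)
    n_hom_a1 = (g == 2).sum(axis=0)
    n_hom_a2 = (g == 0).sum(axis=0)
    return np.array(
        [
            hwe_exact_pvalue(int(h), int(x), int(y))
            for h, x, y in zip(n_het, n_hom_a1, n_hom_a2)
        ]
    )


def drop_duplicate_markers(panel: SnpPanel) -> tuple[SnpPanel, int]:
    """Drop markers with a repeated id or repeated (chrom, pos); keep first."""
    mk = panel.markers
    keep = ~(mk["snp"].duplicated() | mk.duplicated(subset=["chrom", "pos"]))
    removed = int((~keep).sum())
    if removed == 0:
        return panel, 0
    return panel.subset(marker_idx=np.flatnonzero(keep.to_numpy())), removed


def filter_individuals_missing(
    panel: SnpPanel, threshold: float = 0.10
) -> tuple[SnpPanel, QcReport]:
    """Remove individuals missing strictly more than ``threshold`` of calls."""
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    rep = QcReport(
        n_individuals_before=panel.n_individuals, n_markers_before=panel.n_markers
    )
    frac = panel.missing_mask().mean(axis=1) if panel.n_markers else np.zeros(
        panel.n_individuals
    )
    keep = frac <= threshold
    rep.removed_individuals_missing = int((~keep).sum())
    rep.removed_individual_ids = [
        panel.ids[i] for i in np.flatnonzero(~keep)
    ]
    out = panel.subset(individuals=[panel.ids[i] for i in np.flatnonzero(keep)])
    rep.n_individuals_after = out.n_individuals
    rep.n_markers_after = out.n_markers
    return out, rep


def filter_snps(
    panel: SnpPanel,
    miss_threshold: float = 0.10,
    hwe_alpha: float = 1e-6,
    maf_threshold: float = 0.005,
) -> tuple[SnpPanel, QcReport]:
    """Marker filters, applied in order: duplicates, missingness, HWE, MAF."""
    rep = QcReport(
        n_individuals_before=panel.n_individuals, n_markers_before=panel.n_markers
    )
    panel, rep.removed_duplicates = drop_duplicate_markers(panel)

    miss = panel.missing_mask().mean(axis=0)
    keep = miss <= miss_threshold
    rep.removed_snp_missing = int((~keep).sum())
    panel = panel.subset(marker_idx=np.flatnonzero(keep))

    pvals = hwe_pvalues(panel)
    keep = pvals >= hwe_alpha
    rep.removed_hwe = int((~keep).sum())
    panel = panel.subset(marker_idx=np.flatnonzero(keep))

    freq = panel.allele_freq()
    maf = np.fmin(freq, 1 - freq)
    keep = ~(np.isnan(maf) | (maf < maf_threshold))
    rep.removed_maf = int((~keep).sum())
    panel = panel.subset(marker_idx=np.flatnonzero(keep))

    rep.n_individuals_after = panel.n_individuals
    rep.n_markers_after = panel.n_markers
    return panel, rep


def qc_panel(
    panel: SnpPanel,
    mind: float = 0.10,
    geno: float = 0.10,
    hwe: float = 1e-6,
    maf: float = 0.005,
) -> tuple[SnpPanel, QcReport]:
    """Full QC: individual missingness then the marker filter chain."""
    panel, rep_ind = filter_individuals_missing(panel, mind)
    out, rep = filter_snps(panel, geno, hwe, maf)
    rep.n_individuals_before = rep_ind.n_individuals_before
    rep.removed_individuals_missing = rep_ind.removed_individuals_missing
    rep.removed_individual_ids = rep_ind.removed_individual_ids
    rep.n_individuals_after = out.n_individuals
    return out, rep


def intersect_panels(
    parents: SnpPanel, offspring: SnpPanel
) -> tuple[SnpPanel, SnpPanel]:
    """Restrict both panels to markers sharing id and allele pair.

    A marker whose A1/A2 are swapped between panels is kept, with the
    offspring dosage recoded as ``2 - d`` so both count the same allele.
    Output marker order follows the parents panel.
    """
    mk_p = parents.markers.set_index("snp")
    mk_o = offspring.markers.set_index("snp")
    common = [s for s in mk_p.index if s in mk_o.index]
    keep_p, keep_o, flip = [], [], []
    pos_p = {s: i for i, s in enumerate(parents.markers["snp"])}
    pos_o = {s: i for i, s in enumerate(offspring.markers["snp"])}
    for s in common:
        a1p, a2p = mk_p.loc[s, ["a1", "a2"]]
        a1o, a2o = mk_o.loc[s, ["a1", "a2"]]
        if (a1p, a2p) == (a1o, a2o):
            keep_p.append(pos_p[s]); keep_o.append(pos_o[s]); flip.append(False)
        elif (a1p, a2p) == (a2o, a1o):
            keep_p.append(pos_p[s]); keep_o.append(pos_o[s]); flip.append(True)
    if not keep_p:
        raise ValueError("no common markers between panels")
    out_p = parents.subset(marker_idx=keep_p)
    out_o = offspring.subset(marker_idx=keep_o)
    flip = np.asarray(flip)
    if flip.any():
        g = out_o.geno
        cols = np.flatnonzero(flip)
        block = g[:, cols]
        block[block != MISSING] = 2 - block[block != MISSING]
        g[:, cols] = block
        out_o.markers.loc[flip, ["a1", "a2"]] = out_o.markers.loc[
            flip, ["a2", "a1"]
        ].to_numpy()
    return out_p, out_o
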