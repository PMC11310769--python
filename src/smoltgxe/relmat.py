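"""Pedigree (A), genomic (VanRaden G) and single-step (H) relationship matrices.

The A matrix comes from the tabular recursion over a chronologically sorted
pedigree; its inverse from Henderson's rules with inbreeding (a dense solve is
available as a cross-check). The genomic matrix is VanRaden method 1,
G = ZZ' / (2 Σ p(1-p)) with Z the 2p-centered dosage matrix. The single-step
inverse augments A^-1 on the genotyped block with tau*G*^-1 - omega*A22^-1,
where G* blends the raw genomic matrix with A22 for invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .pedigree import Pedigree
from .plinkio import MISSING, SnpPanel


@dataclass
class RelMatrix:
    """Symmetric relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray
    kind: str = "A"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape inconsistent with id list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")
        self.values = (v + v.T) / 2

    def submatrix(self, subjects: list[str]) -> "RelMatrix":
        pos = {ind: i for i, ind in enumerate(self.ids)}
        idx = np.array([pos[s] for s in subjects])
        return RelMatrix(list(subjects), self.values[np.ix_(idx, idx)], self.kind)

    def write_triplets(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# kind=" + self.kind + "\n")
            fh.write("# ids=" + ",".join(self.ids) + "\n")
            n = len(self.ids)
            for i in range(n):
                for j in range(i + 1):
                    fh.write(f"{i}\t{j}\t{self.values[i, j]:.10g}\n")


def a_matrix(pedigree: Pedigree, subjects: list[str] | None = None) -> RelMatrix:
    """Numerator relationship matrix by the tabular method.

    Unknown parents are unrelated, non-inbred founders. Returns the full
    matrix, or its submatrix for ``subjects``.
    """
    ped = pedigree.sorted_topologically()
    ids = ped.ids
    pos = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    sire_idx = np.array([pos.get(s, -1) for s in ped.table["sire"]])
    dam_idx = np.array([pos.get(d, -1) for d in ped.table["dam"]])
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    out = RelMatrix(ids, A, "A")
    return out.submatrix(subjects) if subjects is not None else out


def inbreeding(pedigree: Pedigree) -> pd.Series:
    ped = pedigree.sorted_topologically()
    A = a_matrix(ped)
    return pd.Series(np.diag(A.values) - 1.0, index=A.ids)


def a_inverse(pedigree: Pedigree) -> RelMatrix:
    """A^-1 by Henderson's rules, with inbreeding from the tabular A."""
    ped = pedigree.sorted_topologically()
    ids = ped.ids
    pos = {ind: i for i, ind in enumerate(ids)}
    n = len(ids)
    F = inbreeding(ped).to_numpy()
    Ainv = np.zeros((n, n))
    for i, rec in enumerate(ped.table.itertuples()):
        s = pos.get(rec.sire, -1)
        d = pos.get(rec.dam, -1)
        fs = F[s] if s >= 0 else 0.0
        fd = F[d] if d >= 0 else 0.0
        # Mendelian-sampling variance given the known parents
        dvar = 1.0 - 0.25 * (1 + fs) * (s >= 0) - 0.25 * (1 + fd) * (d >= 0)
        alpha = 1.0 / dvar
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= alpha / 2
                Ainv[p, i] -= alpha / 2
        if s >= 0:
            Ainv[s, s] += alpha / 4
        if d >= 0:
            Ainv[d, d] += alpha / 4
        if s >= 0 and d >= 0:
            Ainv[s, d] += alpha / 4
            Ainv[d, s] += alpha / 4
    return RelMatrix(ids, Ainv, "A_inverse")


def grm_vanraden(panel: SnpPanel, freqs=None) -> RelMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Missing dosages are mean-imputed to 2p before centering. ``freqs`` is a
    per-marker A1 frequency vector, or None to use the observed panel
    frequencies.
    """
    p = panel.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    het = 2 * p * (1 - p)
    if np.any(np.isnan(p)) or np.any(het <= 0):
        bad = panel.markers["snp"][np.isnan(p) | (het <= 0)].tolist()
        raise ValueError(
            f"monomorphic or all-missing markers (zero 2p(1-p)): {bad[:5]} "
            "— run the MAF filter first or supply frequencies"
        )
    Z = panel.geno.astype(float)
    Z[panel.geno == MISSING] = np.nan
    Z = np.where(np.isnan(Z), 2 * p, Z) - 2 * p
    G = (Z @ Z.T) / het.sum()
    return RelMatrix(list(panel.ids), G, "G_raw")


def blend_and_h_inverse(
    A: RelMatrix,
    G_raw: RelMatrix,
    genotyped_ids: list[str],
    alpha: float = 0.95,
    tau: float = 1.0,
    omega: float = 1.0,
) -> tuple[RelMatrix, RelMatrix]:
    """Blend G with A22 and assemble the single-step H inverse.

    G* = alpha*G_raw + (1-alpha)*A22;
    H^-1 = A^-1 + [0 0; 0 tau*G*^-1 - omega*A22^-1] on the genotyped block.
    """
    pos = {ind: i for i, ind in enumerate(A.ids)}
    missing = [g for g in genotyped_ids if g not in pos]
    if missing:
        raise ValueError(f"genotyped ids not in A: {missing[:5]}")
    g_idx = np.array([pos[g] for g in genotyped_ids])
    A22 = A.values[np.ix_(g_idx, g_idx)]
    Gr = G_raw.submatrix(list(genotyped_ids)).values
    Gb = alpha * Gr + (1 - alpha) * A22
    try:
        c = linalg.cho_factor(Gb)
        Gb_inv = linalg.cho_solve(c, np.eye(len(g_idx)))
    except linalg.LinAlgError as exc:
        raise ValueError(
            "blended G not invertible — use a smaller alpha"
        ) from exc
    A22_inv = linalg.inv(A22)
    Ainv = np.linalg.inv(A.values)
    H_inv = Ainv.copy()
    H_inv[np.ix_(g_idx, g_idx)] += tau * Gb_inv - omega * A22_inv
    return (
        RelMatrix(list(genotyped_ids), Gb, "G_blended"),
        RelMatrix(list(A.ids), H_inv, "H_inverse"),
    )


def h_matrix(
    A: RelMatrix,
    G_raw: RelMatrix,
    genotyped_ids: list[str],
    alpha: float = 0.95,
    tau: float = 1.0,
    omega: float = 1.0,
) -> RelMatrix:
    """Explicit H (inverse of the single-step H^-1), ordered as A."""
    _, H_inv = blend_and_h_inverse(A, G_raw, genotyped_ids, alpha, tau, omega)
    return RelMatrix(list(A.ids), np.linalg.inv(H_inv.values), "H")


def matrix_element_correlations(A: RelMatrix, G: RelMatrix) -> dict[str, float]:
    """Pearson correlation of diagonal and off-diagonal elements of A vs G
    over the individuals common to both (in G's order)."""
    common = [i for i in G.ids if i in set(A.ids)]
    a = A.submatrix(common).values
    g = G.submatrix(common).values
    n = len(common)
    iu = np.triu_indices(n, k=1)

    def _corr(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    return {
        "diag": _corr(np.diag(a), np.diag(g)),
        "offdiag": _corr(a[iu], g[iu]),
    }
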