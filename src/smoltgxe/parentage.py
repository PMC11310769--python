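"""Pedigree reconstruction from SNP genotypes.

Primary rule: opposite homozygosity (OH). A true parent and its offspring can
never be homozygous for different alleles at the same locus (barring
genotyping error), so the candidate sire/dam with the lowest OH count is the
tentative parent. A tentative pair is accepted only when both OH rates fall
under a threshold AND the pair appears in the breeder's known-matings list;
otherwise a per-pair transmission likelihood decides, or the offspring stays
unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .plinkio import MISSING, SnpPanel

OH_CONFIRMED = "oh_confirmed"
LIKELIHOOD_ASSIGNED = "likelihood_assigned"
UNASSIGNED = "unassigned"


@dataclass
class ParentAssignment:
    offspring: str
    sire: str | None
    dam: str | None
    oh_sire: int
    oh_dam: int
    status: str


def oh_count(g1: np.ndarray, g2: np.ndarray) -> int:
    """Loci where one genotype is 0 and the other 2, both non-missing."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if g1.shape != g2.shape:
        raise ValueError(f"length mismatch: {g1.shape} vs {g2.shape}")
    return int((((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0))).sum())


def _oh_matrices(offspring: SnpPanel, parents: SnpPanel):
    """OH counts and jointly-typed-locus counts, offspring x parents."""
    o, p = offspring.geno, parents.geno
    o0 = (o == 0).astype(np.float32)
    o2 = (o == 2).astype(np.float32)
    p0 = (p == 0).astype(np.float32)
    p2 = (p == 2).astype(np.float32)
    oh = o0 @ p2.T + o2 @ p0.T
    typed = (o != MISSING).astype(np.float32) @ (p != MISSING).astype(np.float32).T
    return oh.astype(np.int64), typed.astype(np.int64)


def _mendel_table(error_rate: float) -> np.ndarray:
    """P(observed offspring dosage | sire dosage, dam dosage).

    Mendelian transmission from the parents' (assumed true) genotypes,
    followed by symmetric perturbation of the offspring call: with
    probability e, 0->1, 2->1, and 1 -> 0 or 2 with equal odds.
    """
    trans = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])  # P(allele | dosage)
    true_p = np.zeros((3, 3, 3))
    for s in range(3):
        for d in range(3):
            for a in range(2):
                for b in range(2):
                    true_p[s, d, a + b] += trans[s, a] * trans[d, b]
    e = error_rate
    err = np.array(
        [
            [1 - e, e, 0.0],
            [e / 2, 1 - e, e / 2],
            [0.0, e, 1 - e],
        ]
    )  # err[true, obs]
    return np.einsum("sdt,to->sdo", true_p, err)


def likelihood_assign(
    offspring_geno: np.ndarray,
    candidates: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]],
    error_rate: float = 0.01,
    margin: float = 10.0,
) -> tuple[tuple[str, str] | None, dict[tuple[str, str], float]]:
    """Max-likelihood (sire, dam) pair under Mendelian transmission + error.

    Returns the winning pair — or None when the best log-likelihood does not
    beat the runner-up by ``margin`` natural-log units (a single candidate
    wins outright if its likelihood is finite) — and the per-pair log-likelihoods.
    """
    table = _mendel_table(error_rate)
    with np.errstate(divide="ignore"):
        log_table = np.log(table)
    o = np.asarray(offspring_geno)
    obs = o != MISSING
    lls: dict[tuple[str, str], float] = {}
    for pair, (gs, gd) in candidates.items():
        m = obs & (gs != MISSING) & (gd != MISSING)
        lls[pair] = float(log_table[gs[m], gd[m], o[m]].sum())
    ranked = sorted(lls.items(), key=lambda kv: kv[1], reverse=True)
    best_pair, best_ll = ranked[0]
    if not np.isfinite(best_ll):
        return None, lls
    if len(ranked) > 1 and best_ll - ranked[1][1] < margin:
        return None, lls
    return best_pair, lls


def assign_parents(
    offspring: SnpPanel,
    sires: SnpPanel,
    dams: SnpPanel,
    known_matings: set[tuple[str, str]],
    oh_rate_threshold: float = 0.01,
    error_rate: float = 0.01,
    likelihood_margin: float = 10.0,
) -> list[ParentAssignment]:
    """Assign a (sire, dam) pair to every offspring.

    Minimum-OH pair accepted when both OH rates are at or under the threshold,
    the pair is a known mating, and neither minimum is tied; otherwise the
    likelihood stage searches the known matings.
    """
    if sires.n_individuals == 0 or dams.n_individuals == 0:
        raise ValueError("empty candidate parent panel")
    oh_s, typed_s = _oh_matrices(offspring, sires)
    oh_d, typed_d = _oh_matrices(offspring, dams)
    sire_pos = {s: i for i, s in enumerate(sires.ids)}
    dam_pos = {d: i for i, d in enumerate(dams.ids)}
    known_pairs = {
        (s, d) for s, d in known_matings if s in sire_pos and d in dam_pos
    }
    cand_geno = {
        (s, d): (sires.geno[sire_pos[s]], dams.geno[dam_pos[d]])
        for s, d in known_pairs
    }
    out: list[ParentAssignment] = []
    for i, oid in enumerate(offspring.ids):
        js = int(np.argmin(oh_s[i]))
        jd = int(np.argmin(oh_d[i]))
        tie_s = int((oh_s[i] == oh_s[i, js]).sum()) > 1
        tie_d = int((oh_d[i] == oh_d[i, jd]).sum()) > 1
        rate_s = oh_s[i, js] / max(typed_s[i, js], 1)
        rate_d = oh_d[i, jd] / max(typed_d[i, jd], 1)
        pair = (sires.ids[js], dams.ids[jd])
        if (
            not tie_s
            and not tie_d
            and rate_s <= oh_rate_threshold
            and rate_d <= oh_rate_threshold
            and pair in known_pairs
        ):
            out.append(
                ParentAssignment(
                    oid, pair[0], pair[1], int(oh_s[i, js]), int(oh_d[i, jd]),
                    OH_CONFIRMED,
                )
            )
            continue
        best, _ = likelihood_assign(
            offspring.geno[i], cand_geno, error_rate, likelihood_margin
        )
        if best is not None:
            out.append(
                ParentAssignment(
                    oid,
                    best[0],
                    best[1],
                    int(oh_s[i, sire_pos[best[0]]]),
                    int(oh_d[i, dam_pos[best[1]]]),
                    LIKELIHOOD_ASSIGNED,
                )
            )
        else:
            out.append(
                ParentAssignment(
                    oid, None, None, int(oh_s[i, js]), int(oh_d[i, jd]), UNASSIGNED
                )
            )
    return out


def assignments_frame(assignments: list[ParentAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": a.offspring,
                "sire": a.sire or "0",
                "dam": a.dam or "0",
                "status": a.status,
                "OH_sire": a.oh_sire,
                "OH_dam": a.oh_dam,
            }
            for a in assignments
        ]
    )


def family_summary(
    assignments: list[ParentAssignment], pheno: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Family structure per environment plus a chi-square homogeneity test.

    The test compares full-sib family-size distributions between the two
    environments over families present in both (df = families - 1).
    ``pheno`` must carry ``id`` and ``env`` columns.
    """
    df = assignments_frame(assignments).merge(
        pheno[["id", "env"]], on="id", how="inner"
    )
    df["family"] = df["sire"] + "x" + df["dam"]
    sizes = df.pivot_table(
        index="family", columns="env", values="id", aggfunc="count", fill_value=0
    )
    envs = list(sizes.columns)
    stats = {
        "n_full_sib_families": int(df["family"].nunique()),
        "n_sire_families": int(df.loc[df["sire"] != "0", "sire"].nunique()),
        "n_dam_families": int(df.loc[df["dam"] != "0", "dam"].nunique()),
    }
    if len(envs) == 2:
        both = sizes[(sizes[envs[0]] > 0) & (sizes[envs[1]] > 0)]
        stats["n_families_both_envs"] = int(len(both))
        if len(both) > 1:
            chi2, p, dof, _ = chi2_contingency(both.to_numpy().T, correction=False)
            stats["chi2"] = float(chi2)
            stats["df"] = int(dof)
            stats["p_value"] = float(p)
    per_env = {e: sizes[e][sizes[e] > 0] for e in envs}
    stats.update(
        {
            f"mean_family_size_{e}": float(per_env[e].mean())
            for e in envs
            if len(per_env[e])
        }
    )
    return sizes.reset_index(), stats
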