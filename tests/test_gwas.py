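"""MLMA-LOCO association: thresholds, LOCO construction, oracle equivalence,
null calibration and power at a major locus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smoltgxe import (
    SimConfig,
    SnpPanel,
    bonferroni_thresholds,
    grm_vanraden,
    loco_grm_set,
    mlma,
    significant_snps,
    simulate_all,
)
from smoltgxe.plinkio import MISSING

from conftest import small_wbw_config


def _panel(geno, chroms):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    mk = pd.DataFrame(
        {
            "snp": [f"m{j}" for j in range(m)],
            "chrom": [str(c) for c in chroms],
            "pos": np.arange(1, m + 1) * 50,
            "a1": "A",
            "a2": "B",
        }
    )
    return SnpPanel([f"i{r}" for r in range(n)], mk, geno)


# ------------------------------------------------------------ thresholds


def test_bonferroni_threshold_values():
    g, c = bonferroni_thresholds(45751, 29)
    assert g == pytest.approx(-np.log10(0.05 / 45751))
    assert c == pytest.approx(-np.log10(0.05 / (45751 / 29)))
    assert g == pytest.approx(5.961, abs=1e-3)
    assert c == pytest.approx(4.499, abs=1e-3)
    g1, c1 = bonferroni_thresholds(20, 1)
    assert g1 == c1 == pytest.approx(-np.log10(0.0025))
    assert bonferroni_thresholds(1, 1)[0] == pytest.approx(-np.log10(0.05))
    with pytest.raises(ValueError):
        bonferroni_thresholds(0, 29)


def test_thresholds_depend_only_on_counts():
    assert bonferroni_thresholds(100, 4) == bonferroni_thresholds(100, 4)
    assert bonferroni_thresholds(100, 4)[0] > bonferroni_thresholds(100, 4)[1]


# ------------------------------------------------------------ LOCO GRMs


def test_loco_uses_only_other_chromosomes():
    rng = np.random.default_rng(0)
    geno = rng.binomial(2, 0.4, size=(10, 20)).astype(np.int8)
    chroms = [1] * 12 + [2] * 8
    panel = _panel(geno, chroms)
    loco = loco_grm_set(panel)
    only_chr2 = grm_vanraden(
        panel.subset(marker_idx=np.arange(12, 20)),
        freqs=panel.allele_freq()[12:],
    )
    np.testing.assert_allclose(loco["1"].values, only_chr2.values, atol=1e-12)


def test_loco_weighted_recombination_equals_full_grm():
    """Sum of LOCO GRMs weighted by their heterozygosity denominators equals
    (C-1) times the full-panel GRM numerator identity."""
    rng = np.random.default_rng(1)
    geno = rng.binomial(2, 0.3, size=(8, 30)).astype(np.int8)
    chroms = np.repeat([1, 2, 3], 10)
    panel = _panel(geno, chroms)
    loco = loco_grm_set(panel)
    p = panel.allele_freq()
    het = 2 * p * (1 - p)
    full = grm_vanraden(panel)
    acc = np.zeros_like(full.values)
    for c, K in loco.items():
        cols = panel.markers["chrom"].astype(str) == c
        d_c = het.sum() - het[cols.to_numpy()].sum()
        acc += d_c * K.values
    np.testing.assert_allclose(acc / (2 * het.sum()), full.values, atol=1e-10)


def test_loco_invariant_to_marker_order_within_chromosome():
    rng = np.random.default_rng(2)
    geno = rng.binomial(2, 0.4, size=(6, 20)).astype(np.int8)
    chroms = [1] * 10 + [2] * 10
    panel = _panel(geno, chroms)
    perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(10)])
    shuffled = panel.subset(marker_idx=perm)
    a = loco_grm_set(panel)
    b = loco_grm_set(shuffled)
    for c in a:
        np.testing.assert_allclose(a[c].values, b[c].values, atol=1e-12)


def test_loco_single_chromosome_errors():
    panel = _panel(np.ones((3, 4), dtype=np.int8), [1, 1, 1, 1])
    with pytest.raises(ValueError, match="2 chromosomes"):
        loco_grm_set(panel)


# ------------------------------------------------------------ MLMA


def _null_scan(seed=11):
    cfg = SimConfig(
        seed=seed, n_snps=4000, n_chromosomes=20, n_sires=25, n_dams=45,
        offspring_per_family=12,
        trait_names=("WBW",), trait_means_env1=(88.0,), trait_means_env2=(121.9,),
        G_env1=np.array([[127.1]]), G_env2=np.array([[129.6]]),
        R_env1=np.array([[175.1]]), R_env2=np.array([[591.9]]),
        sex_effect=(-6.57,), tank_sd_env1=(0.0,), tank_sd_env2=(0.0,),
        r_g_across_env=0.62,
        causal_chromosomes=tuple(range(1, 11)),
    )
    _, _, opanel, pheno, _ = simulate_all(cfg)
    sub = pheno[pheno["env"] == "RAS"]
    res = mlma(sub, opanel, "WBW")
    return res[res["chrom"].astype(int) > 10].dropna(subset=["p"])


def test_null_pvalues_uniform_and_calibrated():
    """Markers with no effect, polygenic background on other chromosomes:
    empirical type-I error at 0.05 inside the exact binomial 99% interval and
    the p-value distribution passes a KS uniformity check."""
    null = _null_scan()
    m = len(null)
    assert m == 2000
    emp = int((null["p"] < 0.05).sum())
    lo, hi = stats.binom.interval(0.99, m, 0.05)
    assert lo <= emp <= hi
    assert stats.kstest(null["p"], "uniform").pvalue > 0.01


def test_identity_relationship_reduces_to_linear_regression():
    """With LOCO GRM = I and variance components fixed at (0, sigma2), the
    effect and Wald statistic equal ordinary least squares with known
    residual variance, computed here by explicit projection algebra."""
    rng = np.random.default_rng(4)
    n, m = 120, 10
    geno = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
    chroms = [1] * 5 + [2] * 5
    panel = _panel(geno, chroms)
    sigma2 = 2.5
    y = rng.normal(0, np.sqrt(sigma2), n) + 0.3 * geno[:, 2]
    pheno = pd.DataFrame({"id": panel.ids, "sex": rng.choice(["M", "F"], n), "y": y})
    from smoltgxe.relmat import RelMatrix

    eye = {c: RelMatrix(list(panel.ids), np.eye(n), "I") for c in ("1", "2")}
    res = mlma(pheno, panel, "y", fixed=["sex"], loco_grms=eye,
               fixed_vc=(0.0, sigma2)).set_index("snp")

    X = np.column_stack([np.ones(n), (pheno["sex"] == "M").astype(float)])
    M = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    for j in range(m):
        g = geno[:, j].astype(float)
        eff = float(g @ M @ y) / float(g @ M @ g)
        chi2 = float(g @ M @ y) ** 2 / (float(g @ M @ g) * sigma2)
        row = res.loc[f"m{j}"]
        assert row["effect"] == pytest.approx(eff, rel=1e-8)
        assert row["chi2"] == pytest.approx(chi2, rel=1e-8)
        assert row["p"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-8)


def test_causal_locus_effect_unbiased_and_detected():
    """A locus engineered to explain ~20% of phenotypic variance at n=1500 is
    declared genome-wide significant and its effect estimate is unbiased."""
    hits, rel_errs = 0, []
    reps = 3
    for rep in range(reps):
        rng = np.random.default_rng(900 + rep)
        cfg = small_wbw_config(
            seed=900 + rep, n_sires=25, n_dams=50, offspring_per_family=30,
            n_snps=800, n_chromosomes=8,
        )
        _, _, opanel, pheno, _ = simulate_all(cfg)
        n = opanel.n_individuals
        assert n == 1500
        j = 123
        g = opanel.geno[:, j].astype(float)
        p = g.mean() / 2
        vp_target = 50.0
        b = np.sqrt(0.2 * vp_target / (2 * p * (1 - p)))
        y = g * b + rng.normal(0, np.sqrt(0.8 * vp_target), n)
        df = pd.DataFrame({"id": opanel.ids, "y": y})
        res = mlma(df, opanel, "y", fixed=[])
        thr_g, _ = bonferroni_thresholds(opanel.n_markers, 8)
        row = res.set_index("snp").loc[opanel.markers["snp"].iloc[j]]
        if row["neglog10p"] >= thr_g:
            hits += 1
        rel_errs.append((row["effect"] - b) / b)
    assert hits == reps
    assert abs(np.mean(rel_errs)) < 0.1


def test_zero_variance_marker_flagged():
    rng = np.random.default_rng(6)
    geno = rng.binomial(2, 0.4, size=(40, 8)).astype(np.int8)
    geno[:, 3] = 1  # constant dosage: untestable
    panel = _panel(geno, [1] * 4 + [2] * 4)
    y = rng.normal(0, 1, 40)
    df = pd.DataFrame({"id": panel.ids, "y": y})
    res = mlma(df, panel, "y", fixed=[]).set_index("snp")
    assert res.loc["m3", "flag"] == "untestable"
    assert np.isnan(res.loc["m3", "p"])
    assert (res.drop("m3")["flag"] == "ok").all()


def test_significant_counting():
    res = pd.DataFrame(
        {
            "snp": ["a", "b", "c"],
            "chrom": "1",
            "pos": [1, 2, 3],
            "p": [1.0, 10**-6.5, 10**-5.0],
            "neglog10p": [0.0, 6.5, 5.0],
        }
    )
    counts, tab = significant_snps(res, 5.96, 4.50)
    assert counts == {"genome": 1, "chromosome": 2}
    assert tab["snp"].tolist() == ["b", "c"]
    none, _ = significant_snps(res.assign(neglog10p=0.0, p=1.0), 5.96, 4.50)
    assert none == {"genome": 0, "chromosome": 0}
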