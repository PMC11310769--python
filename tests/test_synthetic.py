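"""Ground-truth properties of the simulator: Mendelian transmission,
genic-variance calibration, cross-environment correlation, culling."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from smoltgxe import SimConfig, apply_cull, condition_factor, simulate_all
from smoltgxe.synth import ConfigError, mate_and_drop, simulate_founders
from smoltgxe.pedigree import Pedigree
from smoltgxe.plinkio import SnpPanel

from conftest import small_wbw_config, wbw_config


def test_founder_counts_and_degenerate_maf():
    cfg = wbw_config(seed=1, n_snps=1000, maf_distribution=0.5)
    ped, panel = simulate_founders(cfg)
    assert len(ped) == 72 + 139  # 211 founders
    assert panel.n_markers == 1000
    freq = panel.allele_freq()
    assert abs(freq.mean() - 0.5) < 0.01
    # binomial(2, 0.5) dosage variance = 0.5 per locus
    assert abs(panel.geno.var(axis=0).mean() - 0.5) < 0.02
    assert ped.founders() == ped.ids


def test_seed_reproducibility():
    a = simulate_all(small_wbw_config(seed=42))
    b = simulate_all(small_wbw_config(seed=42))
    assert np.array_equal(a[2].geno, b[2].geno)
    pd.testing.assert_frame_equal(a[3], b[3])
    c = simulate_all(small_wbw_config(seed=43))
    assert not np.array_equal(a[2].geno, c[2].geno)


def _two_founder_cross(g_sire, g_dam, n_off, seed=0, error=0.0):
    """Many offspring of a single mating with fixed parental genotypes."""
    m = len(g_sire)
    cfg = small_wbw_config(
        seed=seed, n_sires=1, n_dams=1, dams_per_sire=1,
        offspring_per_family=n_off, n_snps=m, n_chromosomes=1,
        genotyping_error_rate=error,
    )
    ped, panel = simulate_founders(cfg)
    panel.geno[0] = np.asarray(g_sire, dtype=np.int8)
    panel.geno[1] = np.asarray(g_dam, dtype=np.int8)
    return mate_and_drop(ped, panel, cfg)


def test_mendelian_certainty():
    """AA x AA -> all dosage 2; AA x aa -> all heterozygous."""
    _, off = _two_founder_cross([2, 2, 0], [2, 0, 0], n_off=50)
    assert (off.geno[:, 0] == 2).all()
    assert (off.geno[:, 1] == 1).all()
    assert (off.geno[:, 2] == 0).all()


def test_het_cross_segregates_1_2_1():
    _, off = _two_founder_cross([1] * 40, [1] * 40, n_off=250, seed=3)
    counts = np.array([(off.geno == d).sum() for d in (0, 1, 2)], dtype=float)
    props = counts / counts.sum()
    # 10,000 draws per class: binomial sampling error ~ 3*sqrt(pq/n) < 0.02
    np.testing.assert_allclose(props, [0.25, 0.5, 0.25], atol=0.02)


def test_pedigree_extended_with_true_parents():
    ped, off = _two_founder_cross([1, 1], [1, 1], n_off=5)
    kids = ped.table[ped.table["sire"] != "0"]
    assert len(kids) == 5
    assert set(kids["sire"]) == {"S0001"} and set(kids["dam"]) == {"D0001"}


def test_zero_residual_no_fixed_effects_phenotype_equals_bv():
    cfg = small_wbw_config(
        seed=9,
        R_env1=np.array([[0.0]]), R_env2=np.array([[0.0]]),
        sex_effect=(0.0,), tank_sd_env1=(0.0,), tank_sd_env2=(0.0,),
        trait_means_env1=(0.0,), trait_means_env2=(0.0,),
    )
    _, _, _, pheno, truth = simulate_all(cfg)
    merged = pheno.merge(truth, on=["id", "env", "sex"])
    bv_home = np.where(
        merged["env"] == "RAS", merged["bv_WBW@RAS"], merged["bv_WBW@loch"]
    )
    np.testing.assert_allclose(merged["WBW"], bv_home, atol=1e-10)


def test_perfect_cross_env_correlation_gives_identical_bvs():
    cfg = small_wbw_config(
        seed=10, r_g_across_env=1.0,
        G_env2=np.array([[127.10]]),  # same scaling in both environments
    )
    _, _, _, _, truth = simulate_all(cfg)
    np.testing.assert_allclose(
        truth["bv_WBW@RAS"], truth["bv_WBW@loch"], rtol=1e-8
    )


def test_realized_genic_variance_and_cross_env_correlation():
    """BV variance tracks the configured Vg (within 5% on average over 50
    replicates) and the BV cross-environment correlation approaches the
    configured r_g."""
    ratios, cors = [], []
    for rep in range(50):
        cfg = small_wbw_config(seed=500 + rep, n_snps=300)
        _, _, _, _, truth = simulate_all(cfg)
        ratios.append(truth["bv_WBW@RAS"].var(ddof=1) / 127.10)
        cors.append(
            np.corrcoef(truth["bv_WBW@RAS"], truth["bv_WBW@loch"])[0, 1]
        )
    assert abs(np.mean(ratios) - 1.0) < 0.05
    # 220 individuals per replicate, 50 replicates: tight on average
    assert abs(np.mean(cors) - 0.62) < 0.05


def test_full_sib_bv_correlation_near_half():
    """Under the additive model full sibs share half their breeding value;
    the sib-pair correlation is noisy per replicate (families are the
    effective sample), so it is checked in aggregate."""
    rs = []
    for rep in range(10):
        cfg = wbw_config(seed=700 + rep, n_snps=400)
        _, _, _, _, truth = simulate_all(cfg)
        pairs_a, pairs_b = [], []
        for _, grp in truth.groupby("family"):
            bv = grp["bv_WBW@RAS"].to_numpy()
            half = len(bv) // 2
            pairs_a.extend(bv[:half])
            pairs_b.extend(bv[half : 2 * half])
        rs.append(np.corrcoef(pairs_a, pairs_b)[0, 1])
    assert abs(np.mean(rs) - 0.5) < 0.05


def test_offspring_midparent_regression_near_one():
    """Regressing offspring on midparent breeding values gives slope ~ 1."""
    cfg = wbw_config(seed=88, n_snps=600)
    ped, fpanel, opanel, pheno, truth = simulate_all(cfg)
    beta = truth.attrs["snp_effects"]
    p0 = truth.attrs["p0"]
    col = truth.attrs["effect_columns"].index("WBW@RAS")
    founder_bv = dict(
        zip(fpanel.ids, (fpanel.geno - 2 * p0) @ beta[:, col])
    )
    kids = ped.table[ped.table["sire"] != "0"]
    mid = np.array(
        [0.5 * (founder_bv[s] + founder_bv[d]) for s, d in zip(kids["sire"], kids["dam"])]
    )
    off_bv = truth.set_index("id").loc[kids["id"], "bv_WBW@RAS"].to_numpy()
    slope = stats.linregress(mid, off_bv).slope
    assert abs(slope - 1.0) < 0.05


def test_environment_split_and_single_sex_tanks():
    cfg = wbw_config(seed=5, n_snps=200)
    _, _, _, pheno, _ = simulate_all(cfg)
    counts = pheno.groupby("env")["id"].count()
    assert abs(counts["RAS"] - counts["loch"]) < 0.1 * counts.sum()
    sexes_per_tank = pheno.groupby("tank")["sex"].nunique()
    assert (sexes_per_tank == 1).all()


def test_condition_factor_convention():
    assert condition_factor(100.0, 20.0) == pytest.approx(1.25)
    assert condition_factor(88.03, 19.05) == pytest.approx(1.2733, abs=1e-4)


def test_cull_identity_order_statistics_and_truncation_mean():
    rng = np.random.default_rng(0)
    pheno = pd.DataFrame({"id": [f"i{k}" for k in range(1000)],
                          "WBW": rng.standard_normal(1000)})
    same, removed = apply_cull(pheno, 0.0, "WBW")
    assert removed == [] and len(same) == 1000

    kept, removed = apply_cull(pheno, 0.05, "WBW")
    assert len(kept) == 950 and len(removed) == 50
    assert kept["WBW"].min() >= pheno.set_index("id").loc[removed, "WBW"].max()

    # survivor mean of a 5%-left-truncated standard normal, by quadrature
    z = stats.norm.ppf(0.05)
    expected = integrate.quad(
        lambda x: x * stats.norm.pdf(x), z, 8
    )[0] / 0.95
    big = pd.DataFrame({"id": range(200_000),
                        "WBW": rng.standard_normal(200_000)})
    survivors, _ = apply_cull(big, 0.05, "WBW")
    assert survivors["WBW"].mean() == pytest.approx(expected, abs=0.01)
    assert expected == pytest.approx(0.1086, abs=0.001)

    with pytest.raises(ConfigError):
        apply_cull(pheno, 1.0, "WBW")


def test_config_validation():
    with pytest.raises(ConfigError, match="positive"):
        wbw_config(seed=0, n_snps=0)
    with pytest.raises(ConfigError, match="mating"):
        wbw_config(seed=0, n_sires=10, n_dams=50, dams_per_sire=2)
    with pytest.raises(ConfigError, match="r_g"):
        wbw_config(seed=0, r_g_across_env=1.5)
    with pytest.raises(ConfigError, match="definite"):
        wbw_config(seed=0, G_env1=np.array([[-1.0]]))
    with pytest.raises(ConfigError, match="maf"):
        wbw_config(seed=0, maf_distribution=0.7)
    with pytest.raises(ConfigError):
        wbw_config(seed=0, genotyping_error_rate=1.0)
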