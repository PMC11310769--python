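"""Shared fixtures: single-trait study configs and the (expensive, session-
scoped) parameter-recovery experiment used by the acceptance checks and the
variance-component property tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from smoltgxe import (
    ModelSpec,
    SimConfig,
    a_matrix,
    derive_params,
    genetic_correlations,
    grm_vanraden,
    gxe_fit,
    reml_fit,
    simulate_all,
)
from smoltgxe.varcomp import prune_nested_factors

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

# the weight-trait scenario: Vg/Vr per environment and the cross-environment
# genetic correlation at which re-ranking was flagged
WBW_VG_ENV1, WBW_VR_ENV1 = 127.10, 175.08
WBW_VG_ENV2, WBW_VR_ENV2 = 129.58, 591.94
WBW_RG = 0.62
TRUE_H2 = WBW_VG_ENV1 / (WBW_VG_ENV1 + WBW_VR_ENV1)  # 0.4206


def wbw_config(seed: int, **overrides) -> SimConfig:
    """Single-trait (whole-body weight) config at the study design scale:
    72 sires x 139 dams, 14 offspring per family (~7 per environment),
    3,000 SNPs on 29 chromosomes."""
    base = dict(
        seed=seed,
        trait_names=("WBW",),
        trait_means_env1=(88.03,),
        trait_means_env2=(121.87,),
        G_env1=np.array([[WBW_VG_ENV1]]),
        G_env2=np.array([[WBW_VG_ENV2]]),
        R_env1=np.array([[WBW_VR_ENV1]]),
        R_env2=np.array([[WBW_VR_ENV2]]),
        sex_effect=(-6.57,),
        tank_sd_env1=(3.0,),
        tank_sd_env2=(0.0,),
        r_g_across_env=WBW_RG,
    )
    base.update(overrides)
    return SimConfig(**base)


def small_wbw_config(seed: int, **overrides) -> SimConfig:
    """Scaled-down single-trait config for fast unit tests."""
    base = dict(
        n_sires=12, n_dams=22, offspring_per_family=10, n_snps=400,
        n_chromosomes=4, n_tanks_per_env=2,
    )
    base.update(overrides)
    return wbw_config(seed, **base)


@pytest.fixture(scope="session")
def recovery_experiment():
    """30 replicate simulations at the study design scale; for each, the
    univariate heritability fit (GRM and pedigree A) in environment 1 and
    the bivariate cross-environment genetic-correlation fit."""
    rows = []
    for rep in range(30):
        cfg = wbw_config(seed=20_000 + rep)
        ped, fpanel, opanel, pheno, truth = simulate_all(cfg)
        G = grm_vanraden(opanel)
        sub = pheno[pheno["env"] == "RAS"]
        fixed = prune_nested_factors(sub, ["sex", "tank"])
        spec = ModelSpec(traits=["WBW"], fixed=fixed)
        fit_g = reml_fit(sub, G, spec)
        dg = derive_params(fit_g).iloc[0]
        A = a_matrix(ped, subjects=sub["id"].tolist())
        fit_a = reml_fit(sub, A, spec)
        da = derive_params(fit_a).iloc[0]
        fit_rg = gxe_fit(pheno, G, "WBW")
        rg = genetic_correlations(fit_rg).iloc[0]
        rows.append(
            {
                "h2_g": dg["h2"], "se_h2_g": dg["SE_h2"],
                "h2_a": da["h2"], "se_h2_a": da["SE_h2"],
                "conv_uni": fit_g.converged,
                "r_g": rg["r_g"], "se_r_g": rg["SE_r_g"],
                "conv_gxe": fit_rg.converged,
            }
        )
    return pd.DataFrame(rows)
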