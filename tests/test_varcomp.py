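"""REML engine: designs, likelihood behaviour, closed-form equivalences,
boundary handling, GxE layout, derived parameters."""

import numpy as np
import pandas as pd
import pytest

from smoltgxe import (
    ModelSpec,
    RelMatrix,
    cgv_percent,
    cv_percent,
    derive_params,
    genetic_correlations,
    gxe_fit,
    heritability,
    reml_fit,
    simulate_all,
)
from smoltgxe.varcomp import DesignError, build_design, prune_nested_factors

from conftest import small_wbw_config


def _identity_rel(ids):
    return RelMatrix(list(ids), np.eye(len(ids)), "I")


def _mixed_tank_pheno(n=90, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "sex": rng.choice(["M", "F"], n),
            "tank": rng.choice(["t1", "t2", "t3"], n),
            "y": rng.normal(50, 5, n),
        }
    )


# ------------------------------------------------------------- design


def test_design_column_count_two_sexes_three_tanks():
    """Intercept + 1 sex contrast + 2 tank contrasts = 4 columns."""
    df = _mixed_tank_pheno()
    spec = ModelSpec(traits=["y"], fixed=["sex", "tank"])
    d = build_design(df, spec, df["id"].tolist())[0]
    assert d["X"].shape[1] == 4
    assert d["x_names"] == ["intercept", "sex[M]", "tank[t2]", "tank[t3]"]


def test_design_single_level_factor_errors():
    df = _mixed_tank_pheno()
    df["batch"] = "only"
    spec = ModelSpec(traits=["y"], fixed=["batch"])
    with pytest.raises(DesignError, match="single level"):
        build_design(df, spec, df["id"].tolist())


def test_design_confounded_factors_error_names_columns():
    df = _mixed_tank_pheno()
    df["copy"] = df["sex"]
    spec = ModelSpec(traits=["y"], fixed=["sex", "copy"])
    with pytest.raises(DesignError, match="aliased"):
        build_design(df, spec, df["id"].tolist())


def test_prune_nested_factors_drops_sex_under_single_sex_tanks():
    df = pd.DataFrame(
        {"sex": ["M", "M", "F", "F"], "tank": ["t1", "t1", "t2", "t2"]}
    )
    assert prune_nested_factors(df, ["sex", "tank"]) == ["tank"]
    mixed = _mixed_tank_pheno()
    assert prune_nested_factors(mixed, ["sex", "tank"]) == ["sex", "tank"]


# ------------------------------------------------------------- REML


def test_reml_identity_relationship_total_variance_matches_ols():
    """With K = I and one record per individual, only Vg + Vr is identified;
    the total equals the closed-form REML residual variance RSS/(n - rank)."""
    df = _mixed_tank_pheno(n=200, seed=2)
    fit = reml_fit(df, _identity_rel(df["id"]), ModelSpec(traits=["y"], fixed=["sex"]))
    X = np.column_stack([np.ones(len(df)), (df["sex"] == "M").astype(float)])
    beta, *_ = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)
    rss = float(((df["y"].to_numpy() - X @ beta) ** 2).sum())
    sigma2 = rss / (len(df) - 2)
    total = float(fit.G.iloc[0, 0] + fit.R.iloc[0, 0])
    assert total == pytest.approx(sigma2, rel=1e-6)


def test_reml_balanced_sire_design_equals_anova_small():
    rng = np.random.default_rng(3)
    ns, k = 12, 8
    y = np.repeat(rng.normal(0, 2.0, ns), k) + rng.normal(0, 5.0, ns * k)
    df = pd.DataFrame({"id": np.repeat([f"s{i}" for i in range(ns)], k), "y": y})
    fit = reml_fit(df, _identity_rel([f"s{i}" for i in range(ns)]),
                   ModelSpec(traits=["y"], fixed=[], tol=1e-12))
    gm = df.groupby("id")["y"].mean().reindex([f"s{i}" for i in range(ns)]).to_numpy()
    msb = k * ((gm - y.mean()) ** 2).sum() / (ns - 1)
    msw = ((y - np.repeat(gm, k)) ** 2).sum() / (ns * (k - 1))
    assert fit.R.iloc[0, 0] == pytest.approx(msw, abs=1e-6)
    assert fit.G.iloc[0, 0] == pytest.approx((msb - msw) / k, abs=1e-6)


def test_loglikelihood_trace_is_monotone():
    cfg = small_wbw_config(seed=31)
    ped, _, opanel, pheno, _ = simulate_all(cfg)
    from smoltgxe import a_matrix

    A = a_matrix(ped, subjects=pheno["id"].tolist())
    fit = reml_fit(pheno, A, ModelSpec(traits=["WBW"], fixed=["tank"]))
    diffs = np.diff(fit.trace)
    assert (diffs >= -1e-9).all()
    assert fit.converged


def test_null_heritability_lands_at_boundary():
    """Data simulated without genetic variance: h2 pinned near zero and the
    boundary is flagged with unavailable SEs."""
    cfg = small_wbw_config(
        seed=17, G_env1=np.array([[1e-12]]), G_env2=np.array([[1e-12]]),
        n_sires=16, n_dams=30, offspring_per_family=12,
    )
    ped, _, opanel, pheno, _ = simulate_all(cfg)
    from smoltgxe import a_matrix

    sub = pheno[pheno["env"] == "RAS"]
    A = a_matrix(ped, subjects=sub["id"].tolist())
    fit = reml_fit(sub, A, ModelSpec(traits=["WBW"], fixed=["tank"]))
    d = derive_params(fit).iloc[0]
    assert d["h2"] < 0.08
    if d["boundary"]:
        assert np.isnan(d["SE_h2"])


def test_gxe_rejects_individual_in_both_environments():
    df = pd.DataFrame(
        {
            "id": ["a", "a", "b"],
            "env": ["E1", "E2", "E1"],
            "sex": "M",
            "tank": ["t1", "t2", "t1"],
            "y": [1.0, 2.0, 3.0],
        }
    )
    with pytest.raises(DesignError, match="both environments"):
        gxe_fit(df, _identity_rel(["a", "b"]), "y")


def test_gxe_residual_covariance_structurally_zero():
    cfg = small_wbw_config(seed=23)
    ped, _, opanel, pheno, _ = simulate_all(cfg)
    from smoltgxe import a_matrix

    A = a_matrix(ped, subjects=pheno["id"].tolist())
    fit = gxe_fit(pheno, A, "WBW")
    assert fit.R.iloc[0, 1] == 0.0
    assert "R[WBW@RAS,WBW@loch]" not in fit.param_names
    # genetic covariance is a free parameter
    assert "G[WBW@RAS,WBW@loch]" in fit.param_names


def test_gxe_perfect_correlation_recovers_near_one():
    cfg = small_wbw_config(
        seed=29, r_g_across_env=1.0, G_env2=np.array([[127.10]]),
        n_sires=20, n_dams=38, offspring_per_family=12,
    )
    ped, _, _, pheno, _ = simulate_all(cfg)
    from smoltgxe import a_matrix

    A = a_matrix(ped, subjects=pheno["id"].tolist())
    fit = gxe_fit(pheno, A, "WBW")
    rg = genetic_correlations(fit)["r_g"].iloc[0]
    assert rg > 0.9


def test_gxe_zero_correlation_centered_at_zero():
    rgs = []
    for rep in range(6):
        cfg = small_wbw_config(
            seed=3100 + rep, r_g_across_env=0.0,
            n_sires=20, n_dams=38, offspring_per_family=12,
        )
        ped, _, _, pheno, _ = simulate_all(cfg)
        from smoltgxe import a_matrix

        A = a_matrix(ped, subjects=pheno["id"].tolist())
        fit = gxe_fit(pheno, A, "WBW")
        rgs.append(genetic_correlations(fit)["r_g"].iloc[0])
    assert abs(np.mean(rgs)) < 0.2


# ------------------------------------------------- derived parameters


def test_scalar_parameter_formulas():
    assert heritability(0.5, 0.5) == pytest.approx(0.5)
    assert cgv_percent(25.0, 50.0) == pytest.approx(10.0)
    assert cv_percent(100.0, 50.0) == pytest.approx(20.0)
    with pytest.raises(ZeroDivisionError):
        cgv_percent(1.0, 0.0)


def test_genetic_correlation_from_components():
    # r_g = covg / sqrt(vg1 * vg2), checked against the fitted components
    df = _mixed_tank_pheno(n=40, seed=5)
    df["y2"] = df["y"] * 0.5 + np.random.default_rng(1).normal(0, 3, len(df))
    fit = reml_fit(df, _identity_rel(df["id"]),
                   ModelSpec(traits=["y", "y2"], fixed=["sex"]))
    out = genetic_correlations(fit).iloc[0]
    G = fit.G
    expected = G.iloc[0, 1] / np.sqrt(G.iloc[0, 0] * G.iloc[1, 1])
    if np.isfinite(out["r_g"]):
        assert out["r_g"] == pytest.approx(np.clip(expected, -1, 1))
    Pm = fit.G + fit.R
    assert out["r_p"] == pytest.approx(
        Pm.iloc[0, 1] / np.sqrt(Pm.iloc[0, 0] * Pm.iloc[1, 1]), abs=1e-9
    )


def test_derive_params_internal_consistency(recovery_experiment):
    """Sampling spread of the heritability estimator agrees with the mean
    delta-method SE, and realized estimates track the A- vs G-source
    expectation (genomic fits no worse than pedigree fits in RMSE)."""
    df = recovery_experiment
    emp_se = df["h2_g"].std(ddof=1)
    mean_se = df["se_h2_g"].mean()
    assert abs(emp_se - mean_se) / mean_se < 0.30
    truth = 127.10 / (127.10 + 175.08)
    rmse_g = np.sqrt(((df["h2_g"] - truth) ** 2).mean())
    rmse_a = np.sqrt(((df["h2_a"] - truth) ** 2).mean())
    assert rmse_g <= rmse_a
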