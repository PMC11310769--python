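"""REML variance components for single- and multi-trait animal models.

The model is the record-stacked linear mixed model

    y = X b + u + e,   u ~ N(0, G0 x K),   e ~ N(0, R0-structured)

where records are grouped by trait, ``K`` is any relationship matrix
(pedigree A, genomic G, or single-step H), ``G0``/``R0`` are trait x trait
(co)variance matrices, and the residual covariance between two traits exists
only for record pairs measured on the same individual. The phenotypic
covariance ``V`` is LINEAR in the (co)variance parameters, which gives exact
first derivatives and an average-information (AI) matrix at the cost of one
Cholesky factorization and one inverse of ``V`` per iteration.

Maximization is by AI updates with Levenberg damping, step halving, and a
backtracking gradient-ascent fallback; a step is accepted only if it does not
decrease the REML log-likelihood, so the likelihood trace is monotone.

The genotype-by-environment model treats the same trait in two environments
as two traits measured on disjoint individuals: the residual covariance is
then structurally absent, which is exactly the zero-residual-covariance
constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .relmat import RelMatrix


class DesignError(ValueError):
    pass


# --------------------------------------------------------------------------
# model specification and design matrices


@dataclass
class ModelSpec:
    """What to fit.

    ``fixed`` lists categorical columns (applied to every trait unless
    overridden per trait via ``fixed_per_trait``); an intercept is always
    included. ``resid_zero_pairs`` forces the residual covariance of the
    named trait pairs to zero even when records share individuals.
    """

    traits: list[str]
    fixed: list[str] = field(default_factory=list)
    fixed_per_trait: dict[str, list[str]] | None = None
    genetic_id: str = "id"
    resid_zero_pairs: list[tuple[str, str]] = field(default_factory=list)
    tol: float = 1e-9
    max_iter: int = 100

    def fixed_for(self, trait: str) -> list[str]:
        if self.fixed_per_trait and trait in self.fixed_per_trait:
            return self.fixed_per_trait[trait]
        return list(self.fixed)


def prune_nested_factors(df: pd.DataFrame, factors: list[str]) -> list[str]:
    """Drop factors whose effect is absorbed by a finer factor.

    A factor is redundant when it is constant within every level of another
    factor (e.g. sex under single-sex tanks). Keeps the finer factor.
    """
    keep = list(factors)
    changed = True
    while changed:
        changed = False
        for coarse in list(keep):
            for fine in keep:
                if fine == coarse:
                    continue
                nun = df.groupby(fine, observed=True)[coarse].nunique()
                if (nun <= 1).all():
                    keep.remove(coarse)
                    changed = True
                    break
            if changed:
                break
    return keep


def _dummy_code(df: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        levels = sorted(df[f].astype(str).unique())
        if len(levels) < 2:
            raise DesignError(f"factor {f!r} has a single level {levels!r}")
        for lev in levels[1:]:
            cols.append((df[f].astype(str) == lev).astype(float).to_numpy())
            names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via pivoted QR
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        aliased = [names[j] for j in piv[rank:]]
        raise DesignError(f"confounded fixed effects, aliased columns: {aliased}")
    return X, names


def build_design(pheno: pd.DataFrame, spec: ModelSpec, k_ids: list[str]):
    """Per-trait response, fixed-effect design, and K-index of each record.

    Records with a missing response are dropped per trait. Every retained
    record's ``genetic_id`` must be present in ``k_ids``.
    """
    pos = {ind: i for i, ind in enumerate(k_ids)}
    per_trait = []
    for t in spec.traits:
        cols = [spec.genetic_id, t] + spec.fixed_for(t)
        sub = pheno[cols].dropna(subset=[t])
        for f in spec.fixed_for(t):
            if sub[f].isna().any():
                raise DesignError(f"missing values in fixed factor {f!r}")
        missing = [g for g in sub[spec.genetic_id].astype(str) if g not in pos]
        if missing:
            raise DesignError(
                f"{len(missing)} records not covered by the relationship "
                f"matrix, e.g. {missing[:3]}"
            )
        X, names = _dummy_code(sub, spec.fixed_for(t))
        idx = np.array([pos[g] for g in sub[spec.genetic_id].astype(str)])
        per_trait.append(
            {
                "trait": t,
                "y": sub[t].to_numpy(dtype=float),
                "X": X,
                "x_names": names,
                "k_idx": idx,
                "ids": sub[spec.genetic_id].astype(str).tolist(),
            }
        )
    return per_trait


# --------------------------------------------------------------------------
# variance structures


class _GenStruct:
    """Genetic (co)variance between trait blocks t and s: theta * K[idx_t, idx_s]."""

    def __init__(self, t, s, rows_t, rows_s, K_ts):
        self.t, self.s = t, s
        self.rows_t, self.rows_s = rows_t, rows_s
        self.K_ts = K_ts
        self.sym = t == s

    def add_to(self, V, theta):
        V[self.rows_t, self.rows_s] += theta * self.K_ts
        if not self.sym:
            V[self.rows_s, self.rows_t] += theta * self.K_ts.T

    def trace_with(self, P):
        tr = float(np.sum(P[self.rows_t, self.rows_s] * self.K_ts))
        return tr if self.sym else 2.0 * tr

    def matvec(self, v):
        out = np.zeros_like(v)
        out[self.rows_t] = self.K_ts @ v[self.rows_s]
        if not self.sym:
            out[self.rows_s] += self.K_ts.T @ v[self.rows_t]
        return out


class _ResDiagStruct:
    """Residual variance of trait t: theta * I on its block."""

    def __init__(self, t, rows_t, n):
        self.t, self.s = t, t
        self.idx = np.arange(rows_t.start, rows_t.stop)
        self.n = n

    def add_to(self, V, theta):
        V[self.idx, self.idx] += theta

    def trace_with(self, P):
        return float(P[self.idx, self.idx].sum())

    def matvec(self, v):
        out = np.zeros_like(v)
        out[self.idx] = v[self.idx]
        return out


class _ResCovStruct:
    """Residual covariance between traits t,s at same-individual record pairs."""

    def __init__(self, t, s, pairs_t, pairs_s):
        self.t, self.s = t, s
        self.p1 = pairs_t
        self.p2 = pairs_s

    def add_to(self, V, theta):
        V[self.p1, self.p2] += theta
        V[self.p2, self.p1] += theta

    def trace_with(self, P):
        return 2.0 * float(P[self.p1, self.p2].sum())

    def matvec(self, v):
        out = np.zeros_like(v)
        out[self.p1] = v[self.p2]
        out[self.p2] += v[self.p1]
        return out


# --------------------------------------------------------------------------
# fit result


@dataclass
class VarCompFit:
    traits: list[str]
    G: pd.DataFrame
    R: pd.DataFrame
    param_names: list[str]
    theta: np.ndarray
    ai_inv: np.ndarray | None
    loglik: float
    trace: list[float]
    converged: bool
    boundary: dict[str, bool]
    n_records: int

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def sampling_var(self, name: str) -> float:
        if self.ai_inv is None:
            return float("nan")
        i = self.param_index(name)
        return float(self.ai_inv[i, i])


def _initial_theta(per_trait, params):
    vp = {}
    for d in per_trait:
        X, y = d["X"], d["y"]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        vp[d["trait"]] = float(r @ r) / dof
    theta = np.empty(len(params))
    for k, (kind, t, s) in enumerate(params):
        if t == s:
            theta[k] = 0.5 * vp[t]
        else:
            theta[k] = 0.1 * np.sqrt(vp[t] * vp[s]) * (0.5 if kind == "R" else 1.0)
    return theta, vp


def _theta_valid(theta, params, traits, floors):
    """Diagonals at/above their floor; G0 and R0 PSD (tiny negatives tolerated)."""
    T = len(traits)
    G0 = np.zeros((T, T))
    R0 = np.zeros((T, T))
    ti = {t: i for i, t in enumerate(traits)}
    for k, (kind, t, s) in enumerate(params):
        M = G0 if kind == "G" else R0
        M[ti[t], ti[s]] = M[ti[s], ti[t]] = theta[k]
        if t == s and theta[k] < floors[t] * 0.999:
            return False
    for M in (G0, R0):
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-8 * max(w.max(), 1e-300):
            return False
    return True


def reml_fit(
    pheno: pd.DataFrame, relmatrix: RelMatrix, spec: ModelSpec
) -> VarCompFit:
    """AI-REML fit of the (multi-trait) animal model.

    Raises ``DesignError`` for invalid designs; non-convergence within
    ``spec.max_iter`` returns partial estimates with ``converged=False``.
    """
    per_trait = build_design(pheno, spec, relmatrix.ids)
    traits = spec.traits
    T = len(traits)
    K = relmatrix.values

    # record layout: trait-major blocks
    offsets, rows = [], []
    n = 0
    for d in per_trait:
        offsets.append(n)
        rows.append(slice(n, n + len(d["y"])))
        n += len(d["y"])
    y = np.concatenate([d["y"] for d in per_trait])
    X = linalg.block_diag(*[d["X"] for d in per_trait])

    # parameters: all genetic (co)variances; residual variances; residual
    # covariances only where records share individuals and not constrained
    zero_pairs = {frozenset(p) for p in spec.resid_zero_pairs}
    params: list[tuple[str, str, str]] = []
    structs = []
    for i in range(T):
        for j in range(i, T):
            t, s = traits[i], traits[j]
            K_ts = K[np.ix_(per_trait[i]["k_idx"], per_trait[j]["k_idx"])]
            params.append(("G", t, s))
            structs.append(_GenStruct(t, s, rows[i], rows[j], K_ts))
    for i in range(T):
        params.append(("R", traits[i], traits[i]))
        structs.append(_ResDiagStruct(traits[i], rows[i], n))
    for i in range(T):
        for j in range(i + 1, T):
            t, s = traits[i], traits[j]
            if frozenset((t, s)) in zero_pairs:
                continue
            ids_i = per_trait[i]["ids"]
            ids_j = {ind: r for r, ind in enumerate(per_trait[j]["ids"])}
            p1, p2 = [], []
            for r, ind in enumerate(ids_i):
                if ind in ids_j:
                    p1.append(offsets[i] + r)
                    p2.append(offsets[j] + ids_j[ind])
            if p1:
                params.append(("R", t, s))
                structs.append(_ResCovStruct(t, s, np.array(p1), np.array(p2)))

    theta, vp = _initial_theta(per_trait, params)
    floors = {t: 1e-8 * vp[t] for t in traits}
    p = len(params)

    def build_V(th):
        V = np.zeros((n, n))
        for k in range(p):
            structs[k].add_to(V, th[k])
        return V

    def loglik_terms(th):
        """(ll, cho, Py, P) or None if V not PD."""
        V = build_V(th)
        try:
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetV = 2.0 * float(np.log(np.diag(cho[0])).sum())
        VX = linalg.cho_solve(cho, X, check_finite=False)
        XtVX = X.T @ VX
        try:
            cxx = linalg.cho_factor(XtVX, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdetXVX = 2.0 * float(np.log(np.diag(cxx[0])).sum())
        Vy = linalg.cho_solve(cho, y, check_finite=False)
        XtVy = X.T @ Vy
        Py = Vy - VX @ linalg.cho_solve(cxx, XtVy, check_finite=False)
        ll = -0.5 * (logdetV + logdetXVX + float(y @ Py))
        return ll, cho, VX, cxx, Py

    def full_P(cho, VX, cxx):
        L = cho[0]
        Vi, info = linalg.lapack.dpotri(L, lower=True)
        if info != 0:
            raise linalg.LinAlgError("dpotri failed")
        Vi = np.tril(Vi) + np.tril(Vi, -1).T
        M = linalg.cho_solve(cxx, VX.T, check_finite=False)
        return Vi - VX @ M

    state = loglik_terms(theta)
    if state is None:
        raise DesignError("initial variance structure not positive definite")
    ll = state[0]
    trace_ll = [ll]
    converged = False

    for _ in range(spec.max_iter):
        _, cho, VX, cxx, Py = state
        P = full_P(cho, VX, cxx)
        W = np.column_stack([structs[k].matvec(Py) for k in range(p)])
        score = np.array(
            [
                -0.5 * (structs[k].trace_with(P) - float(Py @ W[:, k]))
                for k in range(p)
            ]
        )
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        AI = (AI + AI.T) / 2

        # propose an AI step, with damping / halving / gradient fallback
        theta_prev = theta.copy()
        accepted = False
        lam = 0.0
        for _damp in range(6):
            try:
                delta = np.linalg.solve(AI + lam * np.diag(np.diag(AI)) + 1e-12 * np.eye(p), score)
            except np.linalg.LinAlgError:
                lam = max(lam * 10, 1e-4)
                continue
            step = 1.0
            for _half in range(12):
                cand = theta + step * delta
                # clamp diagonals at their floor
                clamped = cand.copy()
                for k, (kind, t, s) in enumerate(params):
                    if t == s and clamped[k] < floors[t]:
                        clamped[k] = floors[t]
                if _theta_valid(clamped, params, traits, floors):
                    new_state = loglik_terms(clamped)
                    if new_state is not None and new_state[0] >= ll - 1e-10:
                        theta = clamped
                        state = new_state
                        accepted = True
                        break
                step *= 0.5
            if accepted:
                break
            lam = max(lam * 10, 1e-4)
        if not accepted:
            # scaled gradient ascent with backtracking
            g = score / max(np.abs(np.diag(AI)).max(), 1e-12)
            step = 1.0
            for _half in range(25):
                cand = theta + step * g
                for k, (kind, t, s) in enumerate(params):
                    if t == s and cand[k] < floors[t]:
                        cand[k] = floors[t]
                if _theta_valid(cand, params, traits, floors):
                    new_state = loglik_terms(cand)
                    if new_state is not None and new_state[0] >= ll - 1e-10:
                        theta = cand
                        state = new_state
                        accepted = True
                        break
                step *= 0.5
        if not accepted:
            converged = True  # no ascent direction improves: at a (local) optimum
            break

        new_ll = state[0]
        rel_ll = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll = new_ll
        trace_ll.append(ll)
        denom = np.maximum(
            np.abs(theta), np.array([vp[t] * 1e-4 for (_, t, _s) in params])
        )
        rel_par = float(np.max(np.abs(theta - theta_prev) / denom))
        if rel_ll < spec.tol and rel_par < 1e-6:
            converged = True
            break

    # assemble G0 / R0
    ti = {t: i for i, t in enumerate(traits)}
    G0 = np.zeros((T, T))
    R0 = np.zeros((T, T))
    boundary = {}
    for k, (kind, t, s) in enumerate(params):
        M = G0 if kind == "G" else R0
        M[ti[t], ti[s]] = M[ti[s], ti[t]] = theta[k]
        if t == s:
            boundary[f"{kind}[{t},{s}]"] = bool(theta[k] <= floors[t] * 1.0001)

    # AI inverse at the optimum for sampling (co)variances
    _, cho, VX, cxx, Py = state
    P = full_P(cho, VX, cxx)
    W = np.column_stack([structs[k].matvec(Py) for k in range(p)])
    AI = 0.5 * (W.T @ (P @ W))
    AI = (AI + AI.T) / 2
    try:
        ai_inv = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        ai_inv = None

    names = [f"{kind}[{t},{s}]" for (kind, t, s) in params]
    return VarCompFit(
        traits=traits,
        G=pd.DataFrame(G0, index=traits, columns=traits),
        R=pd.DataFrame(R0, index=traits, columns=traits),
        param_names=names,
        theta=theta,
        ai_inv=ai_inv,
        loglik=ll,
        trace=trace_ll,
        converged=converged,
        boundary=boundary,
        n_records=n,
    )


# --------------------------------------------------------------------------
# GxE: same trait in two environments as two traits


def gxe_fit(
    pheno: pd.DataFrame,
    relmatrix: RelMatrix,
    trait: str,
    env_col: str = "env",
    sex_col: str = "sex",
    tank_col: str = "tank",
    genetic_id: str = "id",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> VarCompFit:
    """Bivariate cross-environment REML for one trait.

    Each individual must carry a record in exactly one environment; the
    residual covariance between the two environment-traits is therefore
    structurally zero. Sex is fitted within environment (each
    environment-trait has its own sex effect); tank/pen likewise.
    """
    counts = pheno.groupby(genetic_id)[env_col].nunique()
    if (counts > 1).any():
        bad = counts[counts > 1].index.tolist()
        raise DesignError(
            f"individuals with records in both environments: {bad[:5]}"
        )
    envs = sorted(pheno[env_col].astype(str).unique())
    if len(envs) != 2:
        raise DesignError(f"expected exactly 2 environments, got {envs}")
    wide = pheno.copy()
    wide[env_col] = wide[env_col].astype(str)
    tnames = [f"{trait}@{e}" for e in envs]
    fixed_per_trait = {}
    for e, tn in zip(envs, tnames):
        wide[tn] = np.where(wide[env_col] == e, wide[trait], np.nan)
        fixed_per_trait[tn] = prune_nested_factors(
            wide[wide[env_col] == e], [sex_col, tank_col]
        )
    spec = ModelSpec(
        traits=tnames,
        fixed=[sex_col, tank_col],
        fixed_per_trait=fixed_per_trait,
        genetic_id=genetic_id,
        resid_zero_pairs=[(tnames[0], tnames[1])],
        tol=tol,
        max_iter=max_iter,
    )
    return reml_fit(wide, relmatrix, spec)


# --------------------------------------------------------------------------
# derived genetic parameters


def heritability(vg: float, vr: float) -> float:
    """Narrow-sense heritability Vg / (Vg + Vr)."""
    return vg / (vg + vr)


def cv_percent(vp: float, mean: float) -> float:
    """Coefficient of phenotypic variation, sqrt(Vp)/mean * 100."""
    if mean == 0:
        raise ZeroDivisionError("CV undefined at zero mean")
    return float(np.sqrt(vp) / mean * 100)


def cgv_percent(vg: float, mean: float) -> float:
    """Coefficient of genetic variation, sqrt(Vg)/mean * 100."""
    if mean == 0:
        raise ZeroDivisionError("CGV undefined at zero mean")
    return float(np.sqrt(vg) / mean * 100)


def _delta_se(fit: VarCompFit, names: list[str], grad: np.ndarray) -> float:
    if fit.ai_inv is None:
        return float("nan")
    idx = [fit.param_index(nm) for nm in names]
    C = fit.ai_inv[np.ix_(idx, idx)]
    v = float(grad @ C @ grad)
    return float(np.sqrt(v)) if v >= 0 else float("nan")


def derive_params(
    fit: VarCompFit, means: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-trait h2, Vp, model CV and CGV, with delta-method standard errors.

    Traits at the variance floor get NaN standard errors (the AI matrix is
    degenerate at the boundary).
    """
    rows = []
    for t in fit.traits:
        vg = float(fit.G.loc[t, t])
        vr = float(fit.R.loc[t, t])
        vp = vg + vr
        h2 = heritability(vg, vr)
        at_boundary = fit.boundary.get(f"G[{t},{t}]", False) or fit.boundary.get(
            f"R[{t},{t}]", False
        )
        if at_boundary:
            se_h2 = se_vg = se_vr = float("nan")
        else:
            grad = np.array([vr, -vg]) / vp**2
            se_h2 = _delta_se(fit, [f"G[{t},{t}]", f"R[{t},{t}]"], grad)
            se_vg = float(np.sqrt(fit.sampling_var(f"G[{t},{t}]")))
            se_vr = float(np.sqrt(fit.sampling_var(f"R[{t},{t}]")))
        row = {
            "trait": t,
            "Vg": vg,
            "SE_Vg": se_vg,
            "Vr": vr,
            "SE_Vr": se_vr,
            "Vp": vp,
            "h2": h2,
            "SE_h2": se_h2,
            "boundary": at_boundary,
        }
        if means is not None and t in means:
            row["mean"] = means[t]
            row["CV_model_pct"] = cv_percent(vp, means[t])
            row["CGV_pct"] = cgv_percent(vg, means[t])
        rows.append(row)
    return pd.DataFrame(rows)


def genetic_correlations(fit: VarCompFit) -> pd.DataFrame:
    """Pairwise genetic, residual and phenotypic correlations with SEs."""
    rows = []
    T = len(fit.traits)
    for i in range(T):
        for j in range(i + 1, T):
            t, s = fit.traits[i], fit.traits[j]
            row = {"pair": f"{t}:{s}"}
            for kind, M in (("g", fit.G), ("r", fit.R)):
                v1, v2 = float(M.loc[t, t]), float(M.loc[s, s])
                c = float(M.loc[t, s])
                nm = f"{kind.upper()}[{t},{s}]"
                if v1 <= 0 or v2 <= 0 or nm not in fit.param_names:
                    row[f"r_{kind}"] = float("nan")
                    row[f"SE_r_{kind}"] = float("nan")
                    continue
                r = c / np.sqrt(v1 * v2)
                r = float(np.clip(r, -1.0, 1.0))
                grad = np.array(
                    [-r / (2 * v1), 1.0 / np.sqrt(v1 * v2), -r / (2 * v2)]
                )
                se = _delta_se(
                    fit,
                    [f"{kind.upper()}[{t},{t}]", nm, f"{kind.upper()}[{s},{s}]"],
                    grad,
                )
                row[f"r_{kind}"] = r
                row[f"SE_r_{kind}"] = se
            # phenotypic correlation from summed covariance matrices
            Pm = fit.G + fit.R
            vp1, vp2 = float(Pm.loc[t, t]), float(Pm.loc[s, s])
            cp = float(Pm.loc[t, s])
            row["r_p"] = float(np.clip(cp / np.sqrt(vp1 * vp2), -1, 1))
            rows.append(row)
    return pd.DataFrame(rows)
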