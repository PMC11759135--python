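"""Multi-trait REML variance components and GBLUP prediction.

The animal model is, for traits stacked per individual,

    y = X b + Z g + e,   g ~ N(0, G (x) M),   e ~ N(0, I (x) R),

with X the fixed-effect design (intercept, milk-production status, birth
year), G the blended genomic relationship matrix, M the t x t genetic
(co)variance matrix and R the residual (co)variance matrix. Derived
quantities are the per-trait heritability h2 = M_kk / (M_kk + R_kk) and the
genetic correlation M_kl / sqrt(M_kk M_ll).

REML estimation works in the eigenbasis of G: with G = U D U' the rotated
records are independent across individuals with per-individual covariance
V_i = d_i M + R, so one restricted-likelihood evaluation costs O(n t^3).
(M, R) are parameterized by their Cholesky factors, which keeps every
iterate inside the PSD cone, and the restricted log-likelihood is maximized
with L-BFGS-B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .datatypes import PhenotypeTable, RelationshipMatrix

logger = logging.getLogger("caprigen")

FIXED_FACTORS = ("milk_status", "birth_year")


def fixed_effect_design(
    data: pd.DataFrame, levels: dict[str, list] | None = None
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    """Full-rank fixed-effect design: intercept + treatment-coded factors.

    ``levels`` (per factor, first entry = reference) is learned from the
    data when not given; pass the training-set levels when building the
    design for validation records so coefficients stay aligned. Records at
    levels unseen in training fall back to the reference level (all
    indicator columns zero) with a logged warning.
    """
    if levels is None:
        levels = {f: sorted(data[f].astype(str).unique()) for f in FIXED_FACTORS}
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for factor in FIXED_FACTORS:
        vals = data[factor].astype(str).to_numpy()
        known = set(levels[factor])
        unseen = sorted(set(vals) - known)
        if unseen:
            logger.warning(
                "factor %s: levels %s unseen in training, using reference "
                "adjustment for %d record(s)",
                factor, unseen, int(np.isin(vals, unseen).sum()),
            )
        for lev in levels[factor][1:]:
            cols.append((vals == lev).astype(float))
            names.append(f"{factor}[{lev}]")
    return np.column_stack(cols), names, levels


@dataclass
class VarianceComponents:
    """REML estimates of the genetic and residual (co)variance matrices."""

    trait_names: list[str]
    genetic_cov: np.ndarray
    residual_cov: np.ndarray
    converged: bool = True
    n_iterations: int = 0
    reml_loglik: float = float("nan")

    def __post_init__(self) -> None:
        self.genetic_cov = np.atleast_2d(np.asarray(self.genetic_cov, dtype=float))
        self.residual_cov = np.atleast_2d(np.asarray(self.residual_cov, dtype=float))

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def trait_index(self, trait: str | int) -> int:
        return trait if isinstance(trait, int) else self.trait_names.index(trait)


def heritability(vc: VarianceComponents, trait: str | int = 0) -> float:
    """h2 = VA / (VA + VE) for one trait."""
    k = vc.trait_index(trait)
    va = vc.genetic_cov[k, k]
    ve = vc.residual_cov[k, k]
    if va + ve == 0.0:
        raise ZeroDivisionError("total variance is zero; heritability undefined")
    return float(va / (va + ve))


def genetic_correlation(
    vc: VarianceComponents, t1: str | int = 0, t2: str | int = 1
) -> float:
    """Genetic correlation sigma_g12 / sqrt(sigma2_g1 * sigma2_g2)."""
    i, j = vc.trait_index(t1), vc.trait_index(t2)
    v1, v2 = vc.genetic_cov[i, i], vc.genetic_cov[j, j]
    if v1 <= 0.0 or v2 <= 0.0:
        raise ZeroDivisionError("genetic variance must be positive for both traits")
    return float(vc.genetic_cov[i, j] / np.sqrt(v1 * v2))


def _chol_to_cov(theta: np.ndarray, t: int) -> np.ndarray:
    L = np.zeros((t, t))
    L[np.tril_indices(t)] = theta
    return L @ L.T


def _cov_to_chol(cov: np.ndarray) -> np.ndarray:
    t = cov.shape[0]
    w, u = np.linalg.eigh(cov)
    fixed = u @ np.diag(np.sqrt(np.clip(w, 1e-8, None))) @ u.T
    return np.linalg.cholesky(fixed @ fixed.T + 1e-10 * np.eye(t))[np.tril_indices(t)]


class _RemlProblem:
    """Restricted log-likelihood in the eigenbasis of G."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, G: np.ndarray):
        n, t = Y.shape
        p = X.shape[1]
        d, U = np.linalg.eigh(G)
        # G only needs to be PSD here: a zero eigenvalue (the centered G always
        # has one along the 1-vector) gives V_i = R, which stays PD
        if d.min() < -1e-8 * max(d.max(), 1.0):
            raise linalg.LinAlgError("relationship matrix is not PSD")
        self.d = np.clip(d, 0.0, None)
        self.Yt = U.T @ Y
        Xt = U.T @ X
        self.n, self.t, self.p = n, t, p
        # X_i = I_t (x) x_i', batched as (n, t, t*p)
        self.Xb = np.zeros((n, t, t * p))
        for k in range(t):
            self.Xb[:, k, k * p:(k + 1) * p] = Xt

    def neg_loglik(self, theta: np.ndarray) -> float:
        t = self.t
        k = t * (t + 1) // 2
        M = _chol_to_cov(theta[:k], t)
        R = _chol_to_cov(theta[k:], t)
        V = self.d[:, None, None] * M + R  # (n, t, t)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e30
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)))
        rhs = np.concatenate([self.Yt[:, :, None], self.Xb], axis=2)
        sol = np.linalg.solve(V, rhs)  # V_i^{-1} [y_i, X_i]
        viy = sol[:, :, 0]
        vix = sol[:, :, 1:]
        yVy = float(np.einsum("ik,ik->", self.Yt, viy))
        XVy = np.einsum("ikq,ik->q", self.Xb, viy)
        C = np.einsum("ikq,ikr->qr", self.Xb, vix)
        try:
            cf = linalg.cho_factor(C)
        except linalg.LinAlgError:
            return 1e30
        b = linalg.cho_solve(cf, XVy)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
        yPy = yVy - float(XVy @ b)
        ll = -0.5 * (logdet + logdet_C + yPy)
        return -ll


def fit_reml(
    phenos: PhenotypeTable,
    G: RelationshipMatrix,
    traits: list[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> VarianceComponents:
    """Estimate (M, R) by REML under the multi-trait animal model.

    ``G`` may be the raw (PSD, singular along the 1-vector) VanRaden matrix
    — preferred for estimation, since blending shrinks off-diagonal genetic
    covariances and biases h2 upward by ~1/weight. Fixed effects are milk
    status and birth year plus an intercept. Non-convergence within the
    iteration budget is reported on the returned object, never silently
    ignored.
    """
    traits = list(phenos.trait_names) if traits is None else [
        phenos.trait_names[t] if isinstance(t, int) else t for t in traits
    ]
    t = len(traits)
    if not (1 <= t <= len(phenos.trait_names)):
        raise ValueError("must select between 1 and all available traits")
    Y = np.column_stack([phenos.values(tr) for tr in traits])
    X, _, _ = fixed_effect_design(phenos.data)
    Gm = G.submatrix(phenos.sample_ids)
    prob = _RemlProblem(Y, X, Gm)

    # start from an equal split of the OLS-residual covariance
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    S = np.atleast_2d(np.cov(resid, rowvar=False))
    theta0 = np.concatenate([_cov_to_chol(S / 2.0), _cov_to_chol(S / 2.0)])

    res = optimize.minimize(
        prob.neg_loglik,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": 1e-7},
    )
    if not res.success:
        # line-search failures with finite-difference gradients are polished
        # by a derivative-free restart from the best point found
        res2 = optimize.minimize(
            prob.neg_loglik, res.x, method="Nelder-Mead",
            options={"maxiter": max_iter * 4, "fatol": tol, "xatol": 1e-8},
        )
        if res2.fun <= res.fun:
            res = res2
    k = t * (t + 1) // 2
    M = _chol_to_cov(res.x[:k], t)
    R = _chol_to_cov(res.x[k:], t)
    if not res.success:
        logger.warning("REML did not converge in %d iterations: %s",
                       res.nit, res.message)
    const = -0.5 * (prob.n * t - t * X.shape[1]) * np.log(2.0 * np.pi)
    return VarianceComponents(
        trait_names=traits,
        genetic_cov=M,
        residual_cov=R,
        converged=bool(res.success),
        n_iterations=int(res.nit),
        reml_loglik=float(-res.fun + const),
    )


@dataclass
class MixedModelFit:
    """Solutions of the mixed-model equations on one training set."""

    trait_names: list[str]
    sample_ids: list[str]
    fixed_effect_names: list[str]
    fixed_effects: np.ndarray  # (p, t)
    gebv: np.ndarray  # (n, t), training animals
    residuals: np.ndarray  # (n, t)


def _solve_mme(
    y: np.ndarray,
    X: np.ndarray | None,
    Z: np.ndarray,
    Ginv: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Henderson's MME for one trait; returns (b_hat, g_hat for all animals)."""
    if X is None:
        A = Z.T @ Z + lam * Ginv
        g = linalg.solve(A, Z.T @ y, assume_a="pos")
        return np.zeros(0), g
    top = np.hstack([X.T @ X, X.T @ Z])
    bot = np.hstack([Z.T @ X, Z.T @ Z + lam * Ginv])
    A = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = linalg.solve(A, rhs, assume_a="sym")
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(f"singular mixed-model coefficient matrix: {e}")
    p = X.shape[1]
    return sol[:p], sol[p:]


def gblup_predict(
    phenos_train: PhenotypeTable,
    G_full: RelationshipMatrix,
    vc: VarianceComponents,
    test_ids: list[str],
    trait: str | int = 0,
    fixed_effects: bool = True,
) -> np.ndarray:
    """GEBVs for test animals from training records via the full-G MME.

    All animals in ``G_full`` enter as random effects; training records are
    linked through the incidence matrix Z, so test animals (no records)
    receive predictions through their genomic relationships — identical to
    projecting training-animal solutions with
    G_test,train @ G_train,train^-1.
    """
    k = vc.trait_index(trait)
    sg2 = vc.genetic_cov[k, k]
    se2 = vc.residual_cov[k, k]
    if sg2 <= 0.0:
        raise ZeroDivisionError("genetic variance must be positive for GBLUP")
    lam = se2 / sg2

    all_ids = list(G_full.sample_ids)
    train_idx = G_full.index_of(phenos_train.sample_ids)
    test_idx = G_full.index_of(test_ids)
    y = phenos_train.values(vc.trait_names[k])
    Z = np.zeros((len(train_idx), len(all_ids)))
    Z[np.arange(len(train_idx)), train_idx] = 1.0
    X = fixed_effect_design(phenos_train.data)[0] if fixed_effects else None
    Ginv = linalg.inv(G_full.values)
    _, g = _solve_mme(y, X, Z, Ginv, lam)
    return g[test_idx]


def gblup_project(
    g_train: np.ndarray,
    G_full: RelationshipMatrix,
    train_ids: list[str],
    test_ids: list[str],
) -> np.ndarray:
    """Extend training-animal GEBVs to test animals:
    g_test = G_test,train @ G_train,train^-1 @ g_train."""
    Gtt = G_full.submatrix(train_ids)
    Gxt = G_full.submatrix(test_ids, train_ids)
    return Gxt @ linalg.solve(Gtt, g_train, assume_a="pos")


def fit_gblup(
    phenos: PhenotypeTable,
    G: RelationshipMatrix,
    vc: VarianceComponents,
) -> MixedModelFit:
    """Solve the MME on the training records for every trait in ``vc``."""
    X, names, _ = fixed_effect_design(phenos.data)
    Gm = G.reorder(phenos.sample_ids)
    Ginv = linalg.inv(Gm.values)
    Z = np.eye(len(phenos.sample_ids))
    B, Ghat = [], []
    for k, tr in enumerate(vc.trait_names):
        lam = vc.residual_cov[k, k] / vc.genetic_cov[k, k]
        b, g = _solve_mme(phenos.values(tr), X, Z, Ginv, lam)
        B.append(b)
        Ghat.append(g)
    B = np.column_stack(B)
    Ghat = np.column_stack(Ghat)
    Y = np.column_stack([phenos.values(tr) for tr in vc.trait_names])
    resid = Y - X @ B - Ghat
    return MixedModelFit(
        trait_names=list(vc.trait_names),
        sample_ids=list(phenos.sample_ids),
        fixed_effect_names=names,
        fixed_effects=B,
        gebv=Ghat,
        residuals=resid,
    )
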