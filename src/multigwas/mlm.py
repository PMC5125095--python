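"""Mixed linear model core shared by the three association strategies.

The model is ``y = W v + x b + u + e`` with ``u ~ N(0, sigma_a2 K)`` and
``e ~ N(0, sigma_e2 I)``; ``K`` is a VanRaden genomic relationship matrix
over a random draw of autosomal SNPs.  Variance components come from a
single-kinship REML profiled to a one-dimensional optimization of the
ratio ``delta = sigma_e2 / sigma_a2`` on eigenvalue-rotated data; the SNP
scan then holds them fixed at the global fit (the P3D/EMMAX
approximation), testing each marker with a Wald chi-square on 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import (
    AssocResult,
    GenotypeMatrix,
    KinshipMatrix,
    VarianceComponents,
)

logger = logging.getLogger(__name__)

_P_FLOOR = 5e-324  # smallest positive subnormal double; underflow guard


def compute_kinship(
    G: GenotypeMatrix, n_random: int = 50_000, seed: int = 0
) -> KinshipMatrix:
    """VanRaden relationship matrix from a seeded random draw of SNPs.

    Up to ``n_random`` SNPs are sampled without replacement; monomorphic
    SNPs in the draw are excluded (count logged).  Dosages are centered by
    twice the allele frequency and the cross-product scaled by
    ``sum 2 p (1 - p)``, so the diagonal averages ~1.
    """
    if G.missing_mask.any():
        raise ValueError("kinship requires complete (imputed) genotypes")
    m = G.n_snps
    if n_random >= m:
        idx = np.arange(m)
    else:
        idx = np.sort(np.random.default_rng(seed).choice(m, n_random, replace=False))
    d = G.dosages[:, idx].astype(float)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("kinship: excluded %d monomorphic SNPs from the draw", n_mono)
    if not poly.any():
        raise ValueError("no polymorphic SNPs available for kinship")
    Z = d[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    K = (Z @ Z.T) / denom
    return KinshipMatrix(K, G.snps["snp_id"].iloc[idx[poly]].tolist())


def design_matrix(
    pheno: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "birth_year", "calving_season"),
    pcs: np.ndarray | None = None,
) -> np.ndarray:
    """Fixed-effect design: intercept + dummy-coded categoricals + optional PCs.

    ``pcs`` columns (genotype principal components) model population
    stratification as continuous covariates.
    """
    cols = [np.ones(len(pheno))]
    for name in covariates:
        if name not in pheno.columns:
            continue
        dummies = pd.get_dummies(pheno[name].astype("category"), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
    W = np.column_stack(cols)
    if pcs is not None:
        W = np.column_stack([W, np.asarray(pcs, dtype=float)])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    return W


def stratification_pcs(G: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Top-k principal components of centered dosages (stratification axes)."""
    d = G.dosages.astype(float)
    d -= d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    return u[:, :k] * s[:k]


def _restricted_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    q = xi.size
    denom = xi + delta
    s = float(np.sum(eta2 / denom))
    return 0.5 * (
        q * np.log(q / (2 * np.pi)) - q - q * np.log(s) - float(np.sum(np.log(denom)))
    )


def reml_variance_components(
    y: np.ndarray, W: np.ndarray, K: KinshipMatrix
) -> VarianceComponents:
    """Single-kinship REML via spectral decomposition.

    Projects ``y`` onto the complement of the fixed-effect space, rotates
    by the eigenvectors of the projected kinship and maximizes the
    restricted likelihood over ``delta = sigma_e2 / sigma_a2`` with a
    log-grid plus bounded refinement.  A boundary optimum (h2 pinned near
    0 or 1) is returned with ``boundary=True``.
    """
    y = np.asarray(y, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n = y.size
    c = W.shape[1]
    if W.shape[0] != n or K.n_samples != n:
        raise ValueError("dimension mismatch between y, W and K")
    if np.linalg.matrix_rank(W) < c:
        raise ValueError("W must have full column rank")
    K.check_psd(tol=1e-8)

    evals = np.linalg.eigvalsh(K.values)
    if evals[-1] - evals[0] < 1e-10 * max(1.0, abs(evals[-1])):
        warnings.warn(
            "kinship is numerically proportional to the identity; "
            "variance components are unidentifiable",
            RuntimeWarning,
        )

    # rotate out the fixed effects: restrict K to an explicit orthonormal
    # basis of the complement of span(W), then diagonalize
    Q_full, _ = np.linalg.qr(W, mode="complete")
    B = Q_full[:, c:]  # n x (n - c)
    xi_all, E = np.linalg.eigh(B.T @ K.values @ B)
    q = n - c
    xi = np.clip(xi_all, 0.0, None)
    eta = E.T @ (B.T @ y)
    eta2 = eta**2

    lo, hi = -6.0, 6.0
    grid = np.logspace(lo, hi, 121)
    lls = np.array([_restricted_loglik(d, xi, eta2) for d in grid])
    best = int(np.argmax(lls))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_restricted_loglik(np.exp(t), xi, eta2),
        bounds=(np.log(a), np.log(b)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    ll = _restricted_loglik(delta, xi, eta2)

    boundary = best in (0, grid.size - 1)
    if boundary:
        warnings.warn(
            "REML optimum at the search boundary; variance ratio pinned",
            RuntimeWarning,
        )

    sigma_a2 = float(np.sum(eta2 / (xi + delta)) / q)
    sigma_e2 = delta * sigma_a2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    return VarianceComponents(sigma_a2, sigma_e2, float(h2), float(ll), boundary)


@dataclass
class _RotatedModel:
    """Whitened (V^{-1/2}-rotated) responses and covariates for GLS."""

    Ut: np.ndarray  # eigenvectors of K, transposed
    w: np.ndarray  # 1/sqrt(sigma_a2 * d_i + sigma_e2)
    y_rot: np.ndarray
    W_rot: np.ndarray
    Q: np.ndarray  # thin orthonormal basis of W_rot
    y_resid: np.ndarray  # y_rot residualized on W_rot


def rotate_model(
    y: np.ndarray, W: np.ndarray, K: KinshipMatrix, vc: VarianceComponents
) -> _RotatedModel:
    d, U = np.linalg.eigh(K.values)
    v_diag = vc.sigma_a2 * np.clip(d, 0.0, None) + vc.sigma_e2
    if np.min(v_diag) <= 0:
        raise ValueError("singular phenotypic covariance (both variances zero?)")
    w = 1.0 / np.sqrt(v_diag)
    Ut = U.T
    y_rot = w * (Ut @ y)
    W_rot = w[:, None] * (Ut @ W)
    Q, _ = np.linalg.qr(W_rot)
    y_resid = y_rot - Q @ (Q.T @ y_rot)
    return _RotatedModel(Ut, w, y_rot, W_rot, Q, y_resid)


def gls_fixed_effects(rm: _RotatedModel, X: np.ndarray | None = None):
    """GLS solve for [W, X] on the rotated scale; returns (coef, cov, resid_df)."""
    design = rm.W_rot if X is None else np.column_stack(
        [rm.W_rot, rm.w[:, None] * (rm.Ut @ X)]
    )
    coef, _, rank, _ = np.linalg.lstsq(design, rm.y_rot, rcond=None)
    resid = rm.y_rot - design @ coef
    dof = design.shape[0] - rank
    sigma2 = float(resid @ resid) / max(dof, 1)
    cov = sigma2 * np.linalg.pinv(design.T @ design)
    return coef, cov, dof


def snp_scan(
    y: np.ndarray,
    W: np.ndarray,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    vc: VarianceComponents | None = None,
    exact: bool = False,
) -> list[AssocResult]:
    """Per-SNP mixed-model association scan.

    Default is the P3D/EMMAX approximation: variance components fixed at
    the global REML fit, each SNP tested by GLS Wald chi-square (1 df)
    under ``V = sigma_a2 K + sigma_e2 I``.  ``exact=True`` re-runs REML
    per SNP (small panels only).
    """
    y = np.asarray(y, dtype=float)
    if vc is None:
        vc = reml_variance_components(y, W, K)
    if exact:
        return _snp_scan_exact(y, W, G, K)
    rm = rotate_model(y, W, K, vc)
    n, c = rm.W_rot.shape

    X = G.dosages.astype(float)
    if G.missing_mask.any():
        raise ValueError("scan requires complete (imputed) genotypes")
    X_rot = rm.w[:, None] * (rm.Ut @ X)
    X_resid = X_rot - rm.Q @ (rm.Q.T @ X_rot)

    sxx = np.einsum("ij,ij->j", X_resid, X_resid)
    sxy = X_resid.T @ rm.y_resid
    syy = float(rm.y_resid @ rm.y_resid)

    sigma_p2 = float(np.var(y))
    p_alt = G.allele_freq()

    tol = 1e-10 * max(1.0, float(np.max(sxx, initial=0.0)))
    results: list[AssocResult] = []
    dof = n - c - 1
    for j in range(G.n_snps):
        snp_id = str(G.snps["snp_id"].iloc[j])
        if sxx[j] <= tol:
            results.append(
                AssocResult(snp_id, 0.0, float("nan"), 0.0, 1.0, 0.0, degenerate=True)
            )
            continue
        beta = sxy[j] / sxx[j]
        rss = max(syy - beta * sxy[j], 0.0)
        sigma2 = rss / dof
        if sigma2 <= 0:
            se = 0.0
            chi2 = float("inf")
        else:
            se = float(np.sqrt(sigma2 / sxx[j]))
            chi2 = float((beta / se) ** 2)
        p = max(float(stats.chi2.sf(chi2, df=1)), _P_FLOOR)
        ve = snp_variance_explained(p_alt[j], 1.0 - p_alt[j], beta, sigma_p2)
        results.append(AssocResult(snp_id, float(beta), se, chi2, p, ve))
    return results


def _snp_scan_exact(y, W, G, K) -> list[AssocResult]:
    results = []
    sigma_p2 = float(np.var(y))
    p_alt = G.allele_freq()
    for j in range(G.n_snps):
        x = G.dosages[:, j].astype(float)
        snp_id = str(G.snps["snp_id"].iloc[j])
        if np.ptp(x) == 0:
            results.append(
                AssocResult(snp_id, 0.0, float("nan"), 0.0, 1.0, 0.0, degenerate=True)
            )
            continue
        Wx = np.column_stack([W, x])
        if np.linalg.matrix_rank(Wx) < Wx.shape[1]:
            results.append(
                AssocResult(snp_id, 0.0, float("nan"), 0.0, 1.0, 0.0, degenerate=True)
            )
            continue
        vc_j = reml_variance_components(y, Wx, K)
        rm = rotate_model(y, W, K, vc_j)
        coef, cov, _ = gls_fixed_effects(rm, x[:, None])
        beta = float(coef[-1])
        se = float(np.sqrt(cov[-1, -1]))
        chi2 = (beta / se) ** 2 if se > 0 else float("inf")
        p = max(float(stats.chi2.sf(chi2, df=1)), _P_FLOOR)
        ve = snp_variance_explained(p_alt[j], 1.0 - p_alt[j], beta, sigma_p2)
        results.append(AssocResult(snp_id, beta, se, float(chi2), p, ve))
    return results


def snp_variance_explained(
    p: float, q: float, beta: float, sigma_p2: float
) -> float:
    """Fraction of phenotypic variance explained by one biallelic marker.

    ``2 p q beta^2 / sigma_p2`` for allele frequencies ``p + q = 1`` and
    additive effect ``beta``, clipped to [0, 1].
    """
    if abs(p + q - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    if sigma_p2 <= 0:
        raise ValueError("sigma_p2 must be positive")
    return float(np.clip(2.0 * p * q * beta**2 / sigma_p2, 0.0, 1.0))


__all__ = [
    "compute_kinship",
    "design_matrix",
    "stratification_pcs",
    "reml_variance_components",
    "rotate_model",
    "gls_fixed_effects",
    "snp_scan",
    "snp_variance_explained",
]
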