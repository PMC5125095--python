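"""Independent brute-force oracles used to check the fast implementations.

Every function here recomputes a quantity by the most transparent route
available — full enumeration, dense linear algebra or grid search — and is
deliberately kept independent of the code paths it validates.
"""

from __future__ import annotations

from math import exp, lgamma, log

import numpy as np


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE P by enumerating every heterozygote count of valid parity."""
    n = n_AA + n_Aa + n_aa
    r = 2 * min(n_AA, n_aa) + n_Aa
    if r == 0 or r == 2 * n:
        return 1.0

    def logp(h: int) -> float:
        hr = (r - h) // 2
        hc = n - h - hr
        return (
            lgamma(n + 1) - lgamma(hr + 1) - lgamma(hc + 1) - lgamma(h + 1)
            + h * log(2.0)
            + lgamma(r + 1) + lgamma(2 * n - r + 1) - lgamma(2 * n + 1)
        )

    hs = list(range(r % 2, min(r, 2 * n - r) + 1, 2))
    ps = np.array([exp(logp(h)) for h in hs])
    ps /= ps.sum()
    obs = ps[hs.index(n_Aa)]
    return float(min(1.0, ps[ps <= obs * (1 + 1e-12)].sum()))


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form normal-equations slope Σ(x-x̄)(y-ȳ)/Σ(x-x̄)²."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def vanraden_direct(dosages: np.ndarray) -> np.ndarray:
    """Hand-computed ZZ'/Σ2pq from centered dosages."""
    d = np.asarray(dosages, float)
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    Z = d[:, keep] - 2 * p[keep]
    return (Z @ Z.T) / np.sum(2 * p[keep] * (1 - p[keep]))


def reml_grid_loglik(y, W, K, lam_grid):
    """Restricted log-likelihood over a grid of delta = sigma_e2/sigma_a2.

    Evaluated directly from the dense multivariate-normal restricted
    likelihood (no spectral shortcuts), in the Harville convention that
    includes the +0.5 log|W'W| constant (the same convention as the
    spectral implementation, so the values — not just the argmax — agree):
    l_R = -0.5 [ log|V| + log|W' V^-1 W| - log|W'W| + y' P y ] + const,
    profiled over the overall scale sigma_a2.
    """
    y = np.asarray(y, float)
    W = np.atleast_2d(np.asarray(W, float))
    n, c = W.shape
    q = n - c
    out = []
    for lam in lam_grid:
        Vd = K + lam * np.eye(n)  # V / sigma_a2
        Vi = np.linalg.inv(Vd)
        WtViW = W.T @ Vi @ W
        P = Vi - Vi @ W @ np.linalg.inv(WtViW) @ W.T @ Vi
        yPy = float(y @ P @ y)
        sigma_a2 = yPy / q
        _, ld_V = np.linalg.slogdet(Vd)
        _, ld_W = np.linalg.slogdet(WtViW)
        _, ld_WtW = np.linalg.slogdet(W.T @ W)
        ll = -0.5 * (
            q * np.log(2 * np.pi * sigma_a2) + ld_V + ld_W - ld_WtW + q
        )
        out.append(ll)
    return np.array(out)


def henderson_mme_ebv(y, W, K, sigma_a2, sigma_e2):
    """Dense solve of Henderson's mixed-model equations; returns u-hat."""
    n = len(y)
    Kinv = np.linalg.inv(K)
    top = np.hstack([W.T @ W / sigma_e2, W.T / sigma_e2])
    bot = np.hstack([W / sigma_e2, np.eye(n) / sigma_e2 + Kinv / sigma_a2])
    A = np.vstack([top, bot])
    b = np.concatenate([W.T @ y / sigma_e2, y / sigma_e2])
    sol = np.linalg.solve(A, b)
    return sol[W.shape[1]:]


def two_snp_loglik_from_freqs(counts: np.ndarray, f: np.ndarray) -> float:
    """Observed-data log-likelihood of a 3x3 dosage table given haplotype
    frequencies (AB, Ab, aB, ab) under random mating."""
    f = np.clip(np.asarray(f, float), 1e-12, None)
    cell = np.empty((3, 3))
    cell[2, 2] = f[0] ** 2
    cell[2, 1] = 2 * f[0] * f[1]
    cell[2, 0] = f[1] ** 2
    cell[1, 2] = 2 * f[0] * f[2]
    cell[1, 1] = 2 * f[0] * f[3] + 2 * f[1] * f[2]
    cell[1, 0] = 2 * f[1] * f[3]
    cell[0, 2] = f[2] ** 2
    cell[0, 1] = 2 * f[2] * f[3]
    cell[0, 0] = f[3] ** 2
    return float(np.sum(counts * np.log(np.clip(cell, 1e-300, None))))


def two_snp_em_grid_loglik(counts: np.ndarray, coupling: float) -> float:
    """Observed-data log-likelihood of a 3x3 dosage table at a given
    cis-coupling fraction of the double heterozygotes.

    The coupling fraction c fixes the haplotype frequencies: unambiguous
    genotype cells contribute known haplotypes and the double-het mass is
    split c : (1-c) between AB/ab and Ab/aB.
    """
    base = np.zeros(4)  # AB, Ab, aB, ab
    for gA in range(3):
        for gB in range(3):
            cnt = counts[gA, gB]
            if cnt == 0 or (gA == 1 and gB == 1):
                continue
            for a, b in zip([1] * gA + [0] * (2 - gA), [1] * gB + [0] * (2 - gB)):
                base[(1 - a) * 2 + (1 - b)] += cnt
    ndh = counts[1, 1]
    hap = base + ndh * np.array([coupling, 1 - coupling, 1 - coupling, coupling])
    return two_snp_loglik_from_freqs(counts, hap / hap.sum())


def venn_enumeration(A: set, B: set, C: set) -> dict[str, int]:
    """Region counts by exhaustive per-element membership checks."""
    regions = {k: 0 for k in (
        "snp_only", "block_only", "gene_only",
        "snp_block", "snp_gene", "block_gene", "all_three",
    )}
    for x in A | B | C:
        key = (x in A, x in B, x in C)
        name = {
            (True, False, False): "snp_only",
            (False, True, False): "block_only",
            (False, False, True): "gene_only",
            (True, True, False): "snp_block",
            (True, False, True): "snp_gene",
            (False, True, True): "block_gene",
            (True, True, True): "all_three",
        }[key]
        regions[name] += 1
    regions["union"] = len(A | B | C)
    return regions
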