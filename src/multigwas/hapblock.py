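"""Haplotype-block association strategy.

Blocks of contiguous SNPs in strong pairwise LD are delimited with a
Gabriel-style D' confidence-interval rule inside a 100 kb window, phased
with a standard EM algorithm over compatible haplotype pairs, and tested
with the shared mixed model: the block statistic is the Wald chi-square
(1 df) of the largest-magnitude haplotype effect.  The fraction of
phenotypic variance a block explains uses a two-step statistic: haplotypes
are clustered into two effect groups (G1/G2), each animal is scored by its
count of G2 haplotypes, and the score is treated as a biallelic marker
(``2 p q beta^2 / sigma_p2``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import AssocResult, GenotypeMatrix, KinshipMatrix, VarianceComponents
from .mlm import gls_fixed_effects, rotate_model

_EM_TOL = 1e-6
_EM_MAX_ITER = 1000
_PRUNE_FREQ = 1e-4
_P_FLOOR = 5e-324


@dataclass
class LdStats:
    """Pairwise LD summary from 2-SNP EM haplotype frequencies."""

    r2: float
    dprime: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass
class HaplotypeBlock:
    """A contiguous strong-LD SNP set, optionally phased."""

    name: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    snp_indices: list[int] = field(default_factory=list)
    haplotypes: list[str] = field(default_factory=list)
    frequencies: np.ndarray | None = None
    diplotypes: np.ndarray | None = None  # (n, 2) most-probable haplotype indices
    posteriors: np.ndarray | None = None  # posterior of the best diplotype
    hap_dosages: np.ndarray | None = None  # (n, t) expected haplotype counts

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def length_bp(self) -> int:
        return block_length(self.start, self.end)


def block_length(start: int, end: int) -> int:
    """Block span in bp, defined as ``end - start``."""
    if start >= end:
        raise ValueError("block start must precede end")
    return int(end) - int(start)


def _pair_em(counts: np.ndarray, tol: float = 1e-12, max_iter: int = 500) -> np.ndarray:
    """EM haplotype frequencies (pAB, pAb, paB, pab) from a 3x3 dosage table."""
    n = counts.sum()
    # fixed haplotype contributions; only the double heterozygote is ambiguous
    base = np.zeros(4)
    for gA in range(3):
        for gB in range(3):
            c = counts[gA, gB]
            if c == 0 or (gA == 1 and gB == 1):
                continue
            # allele copies: A-alt count gA splits over the two haplotypes
            a_alleles = [1] * gA + [0] * (2 - gA)
            b_alleles = [1] * gB + [0] * (2 - gB)
            for a, b in zip(a_alleles, b_alleles):
                base[(1 - a) * 2 + (1 - b)] += c
    # base index order: 0 = AB (alt,alt), 1 = Ab, 2 = aB, 3 = ab
    n_dh = counts[1, 1]
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        if n_dh > 0:
            cis = f[0] * f[3]
            trans = f[1] * f[2]
            w = cis / (cis + trans) if cis + trans > 0 else 0.5
        else:
            w = 0.0
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= 2.0 * n
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def _dprime(f: np.ndarray) -> tuple[float, float]:
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    D = f[0] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = D / dmax if dmax > 0 else 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else 0.0
    return float(dprime), float(r2)


_CI_GRID = np.linspace(0.0, 1.0, 101)


def _dprime_ci(counts: np.ndarray, f_hat: np.ndarray) -> tuple[float, float]:
    """Likelihood-based CI for |D'| over a 101-point grid (Haploview style)."""
    pA = f_hat[0] + f_hat[1]
    pB = f_hat[0] + f_hat[2]
    D_hat = f_hat[0] - pA * pB
    sign = 1.0 if D_hat >= 0 else -1.0
    if sign > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax <= 0:
        return 0.0, 1.0

    lls = np.full(_CI_GRID.size, -np.inf)
    for i, d in enumerate(_CI_GRID):
        D = sign * d * dmax
        fAB = pA * pB + D
        fAb = pA * (1 - pB) - D
        faB = (1 - pA) * pB - D
        fab = (1 - pA) * (1 - pB) + D
        fr = np.clip(np.array([fAB, fAb, faB, fab]), 1e-12, None)
        cell = np.empty((3, 3))
        cell[2, 2] = fr[0] ** 2
        cell[2, 1] = 2 * fr[0] * fr[1]
        cell[2, 0] = fr[1] ** 2
        cell[1, 2] = 2 * fr[0] * fr[2]
        cell[1, 1] = 2 * fr[0] * fr[3] + 2 * fr[1] * fr[2]
        cell[1, 0] = 2 * fr[1] * fr[3]
        cell[0, 2] = fr[2] ** 2
        cell[0, 1] = 2 * fr[2] * fr[3]
        cell[0, 0] = fr[3] ** 2
        lls[i] = float(np.sum(counts * np.log(np.clip(cell, 1e-300, None))))

    post = np.exp(lls - lls.max())
    post /= post.sum()
    cdf = np.cumsum(post)
    low = float(_CI_GRID[int(np.searchsorted(cdf, 0.05))])
    high = float(_CI_GRID[min(int(np.searchsorted(cdf, 0.95)), _CI_GRID.size - 1)])
    return low, high


def pairwise_ld(gA: np.ndarray, gB: np.ndarray) -> LdStats:
    """D', r2 and the D' confidence interval for one SNP pair.

    Haplotype frequencies are estimated by 2-SNP EM from unphased dosages;
    pairs with a missing call in either SNP are dropped.
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    ok = (gA >= 0) & (gB >= 0)
    gA, gB = gA[ok], gB[ok]
    if gA.size == 0:
        raise ValueError("no jointly called samples")
    counts = np.zeros((3, 3))
    np.add.at(counts, (gA, gB), 1.0)
    if np.ptp(gA) == 0 or np.ptp(gB) == 0:
        return LdStats(float("nan"), float("nan"), float("nan"), float("nan"), False)
    f = _pair_em(counts)
    dprime, r2 = _dprime(f)
    lo, hi = _dprime_ci(counts, f)
    return LdStats(r2, dprime, lo, hi, True)


@dataclass(frozen=True)
class GabrielThresholds:
    """CI rules for classifying SNP pairs (PLINK 1.7 --blocks defaults)."""

    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    informative_fraction: float = 0.95


def partition_blocks(
    G: GenotypeMatrix,
    window_kb: float = 100.0,
    thresholds: GabrielThresholds = GabrielThresholds(),
) -> list[HaplotypeBlock]:
    """Delimit haplotype blocks by the Gabriel confidence-interval method.

    A pair is *strong LD* when its D' CI lies in [>=strong_ci_low,
    >=strong_ci_high] and *strong recombination* when the CI upper bound
    falls below ``recomb_ci_high``; a span of SNPs becomes a block when its
    bounding pair is strong LD and at least ``informative_fraction`` of its
    informative pairs are strong LD.  Longest spans win; blocks never
    overlap nor exceed the bp window.  Returns boundary-only blocks,
    named ``Hap-<chrom>-N<ordinal>`` in genome order.
    """
    window_bp = window_kb * 1000.0
    blocks: list[HaplotypeBlock] = []
    chroms = G.snps["chrom"].to_numpy()
    pos = G.snps["pos"].to_numpy()

    for chrom in dict.fromkeys(chroms):  # preserve order
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"SNPs on chromosome {chrom} are not position-sorted")
        m = idx.size
        strong = {}
        informative = {}
        for a in range(m):
            for b in range(a + 1, m):
                if p[b] - p[a] > window_bp:
                    break
                ld = pairwise_ld(G.dosages[:, idx[a]], G.dosages[:, idx[b]])
                if not ld.defined:
                    continue
                is_strong = (
                    ld.ci_low >= thresholds.strong_ci_low
                    and ld.ci_high >= thresholds.strong_ci_high
                )
                is_recomb = ld.ci_high < thresholds.recomb_ci_high
                if is_strong or is_recomb:
                    informative[(a, b)] = is_strong
                if is_strong:
                    strong[(a, b)] = True

        candidates = []
        for a in range(m):
            for b in range(a + 1, m):
                if p[b] - p[a] > window_bp:
                    break
                if (a, b) not in strong:
                    continue
                pairs = [
                    informative[(k, l)]
                    for k in range(a, b + 1)
                    for l in range(k + 1, b + 1)
                    if (k, l) in informative
                ]
                if not pairs:
                    continue
                if sum(pairs) / len(pairs) >= thresholds.informative_fraction:
                    candidates.append((a, b, int(p[b] - p[a])))

        candidates.sort(key=lambda t: (-t[2], t[0]))
        used = np.zeros(m, dtype=bool)
        chosen = []
        for a, b, _span in candidates:
            if used[a : b + 1].any():
                continue
            used[a : b + 1] = True
            chosen.append((a, b))
        chosen.sort()
        for k, (a, b) in enumerate(chosen, start=1):
            members = idx[a : b + 1]
            blocks.append(
                HaplotypeBlock(
                    name=f"Hap-{chrom}-N{k}",
                    chrom=str(chrom),
                    start=int(p[a]),
                    end=int(p[b]),
                    snp_ids=G.snps["snp_id"].iloc[members].tolist(),
                    snp_indices=[int(i) for i in members],
                )
            )
    return blocks


def _compatible_pairs(pattern: tuple[int, ...]):
    """All unordered haplotype pairs consistent with one genotype vector."""
    het = [i for i, g in enumerate(pattern) if g == 1]
    base = [1 if g == 2 else 0 for g in pattern]
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    first, rest = het[0], het[1:]
    for bits in itertools.product((0, 1), repeat=len(rest)):
        a = list(base)
        b = list(base)
        a[first], b[first] = 1, 0
        for pos_i, bit in zip(rest, bits):
            a[pos_i], b[pos_i] = bit, 1 - bit
        pairs.append((tuple(a), tuple(b)))
    return pairs


def em_phase(
    G_block: GenotypeMatrix,
    block: HaplotypeBlock | None = None,
    max_snps: int = 25,
    tol: float = _EM_TOL,
    max_iter: int = _EM_MAX_ITER,
    prune_freq: float = _PRUNE_FREQ,
    check_monotone: bool = False,
) -> HaplotypeBlock:
    """EM haplotype inference for one block of unphased genotypes.

    Iterates expectation over all haplotype pairs compatible with each
    genotype vector until the largest frequency change falls below ``tol``
    (or ``max_iter`` sweeps); haplotypes rarer than ``prune_freq`` are then
    pruned and frequencies renormalized.  Per-sample output records the
    most probable diplotype, its posterior, and the expected haplotype
    counts (posterior dosages) used as the association design.
    """
    s = G_block.n_snps
    if s > max_snps:
        raise ValueError(
            f"block has {s} SNPs > enumeration bound {max_snps}; split the block"
        )
    if G_block.missing_mask.any():
        raise ValueError("EM phasing requires complete (imputed) genotypes")
    n = G_block.n_samples

    patterns = [tuple(int(g) for g in row) for row in G_block.dosages]
    uniq: dict[tuple[int, ...], int] = {}
    for pt in patterns:
        uniq[pt] = uniq.get(pt, 0) + 1

    hap_index: dict[tuple[int, ...], int] = {}
    pat_pairs: dict[tuple[int, ...], list[tuple[int, int]]] = {}
    for pt in uniq:
        pairs = []
        for a, b in _compatible_pairs(pt):
            for h in (a, b):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            pairs.append((hap_index[a], hap_index[b]))
        pat_pairs[pt] = pairs
    haps = list(hap_index)
    t = len(haps)

    f = np.full(t, 1.0 / t)
    last_ll = -np.inf
    for _ in range(max_iter):
        counts = np.zeros(t)
        ll = 0.0
        for pt, c in uniq.items():
            pairs = pat_pairs[pt]
            w = np.array(
                [(1.0 if a == b else 2.0) * f[a] * f[b] for a, b in pairs]
            )
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pairs), 1.0 / len(pairs))
                tot = 1.0
            else:
                ll += c * math.log(tot)
                w = w / tot
            for (a, b), wi in zip(pairs, w):
                counts[a] += c * wi
                counts[b] += c * wi
        if check_monotone and ll < last_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        last_ll = ll
        new = counts / (2.0 * n)
        delta = float(np.max(np.abs(new - f)))
        f = new
        if delta < tol:
            break

    # prune rare haplotypes; keep any haplotype a genotype strictly needs
    keep = f >= prune_freq
    for pt, pairs in pat_pairs.items():
        if not any(keep[a] and keep[b] for a, b in pairs):
            best = max(pairs, key=lambda ab: f[ab[0]] * f[ab[1]])
            keep[best[0]] = keep[best[1]] = True
    kept_idx = np.flatnonzero(keep)
    remap = {int(old): new for new, old in enumerate(kept_idx)}
    haps = [haps[i] for i in kept_idx]
    f = f[kept_idx]
    f = f / f.sum()
    order = np.argsort(-f, kind="stable")
    haps = [haps[i] for i in order]
    f = f[order]
    remap2 = {int(old): new for new, old in enumerate(order)}
    final_map = {old: remap2[new] for old, new in remap.items()}
    t = len(haps)

    diplotypes = np.zeros((n, 2), dtype=np.int32)
    posteriors = np.zeros(n)
    dosage = np.zeros((n, t))
    pat_cache: dict[tuple[int, ...], tuple[np.ndarray, tuple[int, int], float]] = {}
    for pt in uniq:
        pairs = [
            (final_map[a], final_map[b])
            for a, b in pat_pairs[pt]
            if a in final_map and b in final_map
        ]
        w = np.array([(1.0 if a == b else 2.0) * f[a] * f[b] for a, b in pairs])
        tot = w.sum()
        w = w / tot if tot > 0 else np.full(len(pairs), 1.0 / len(pairs))
        dos = np.zeros(t)
        for (a, b), wi in zip(pairs, w):
            dos[a] += wi
            dos[b] += wi
        best_i = int(np.argmax(w))
        pat_cache[pt] = (dos, pairs[best_i], float(w[best_i]))
    for i, pt in enumerate(patterns):
        dos, best_pair, post = pat_cache[pt]
        dosage[i] = dos
        diplotypes[i] = best_pair
        posteriors[i] = post

    a1 = G_block.snps["a1"].tolist()
    a2 = G_block.snps["a2"].tolist()
    hap_strings = [
        "".join(a1[j] if h[j] else a2[j] for j in range(s)) for h in haps
    ]

    if block is None:
        pos = G_block.snps["pos"].to_numpy()
        block = HaplotypeBlock(
            name=f"Hap-{G_block.snps['chrom'].iloc[0]}-N1",
            chrom=str(G_block.snps["chrom"].iloc[0]),
            start=int(pos.min()),
            end=int(pos.max()),
            snp_ids=G_block.snps["snp_id"].tolist(),
        )
    block.haplotypes = hap_strings
    block.frequencies = f
    block.diplotypes = diplotypes
    block.posteriors = posteriors
    block.hap_dosages = dosage
    return block


def block_assoc(
    y: np.ndarray,
    W: np.ndarray,
    block: HaplotypeBlock,
    K: KinshipMatrix,
    vc: VarianceComponents,
    use_best_guess: bool = False,
) -> AssocResult:
    """Mixed-model Wald test of a phased block.

    Haplotype effects are estimated jointly by GLS under the global
    variance components, with the most frequent haplotype as baseline; the
    block statistic is ``(beta_max / se)^2`` for the largest-magnitude
    effect, referred to chi-square with 1 df.
    """
    if block.hap_dosages is None:
        raise ValueError("block must be phased first (em_phase)")
    t = block.n_haplotypes
    if t < 2:
        return AssocResult(block.name, 0.0, float("nan"), 0.0, 1.0, 0.0, degenerate=True)
    if use_best_guess:
        H = np.zeros_like(block.hap_dosages)
        for k in range(2):
            np.add.at(H, (np.arange(len(H)), block.diplotypes[:, k]), 1.0)
    else:
        H = block.hap_dosages
    H_d = H[:, 1:]  # haplotypes sorted by frequency; column 0 is the baseline

    rm = rotate_model(np.asarray(y, float), W, K, vc)
    coef, cov, _ = gls_fixed_effects(rm, H_d)
    nh = H_d.shape[1]
    betas = coef[-nh:]
    ses = np.sqrt(np.clip(np.diag(cov)[-nh:], 0.0, None))
    j = int(np.argmax(np.abs(betas)))
    beta, se = float(betas[j]), float(ses[j])
    if se <= 0:
        chi2 = float("inf") if beta != 0 else 0.0
    else:
        chi2 = (beta / se) ** 2
    p = max(float(stats.chi2.sf(chi2, df=1)), _P_FLOOR)
    return AssocResult(block.name, beta, se, float(chi2), p)


def _two_means_1d(values: np.ndarray) -> np.ndarray:
    """Deterministic 1-D 2-means: centers start at the extremes."""
    lo, hi = float(values.min()), float(values.max())
    labels = np.zeros(values.size, dtype=int)
    for _ in range(100):
        new_labels = (np.abs(values - hi) < np.abs(values - lo)).astype(int)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        if labels.any():
            hi = float(values[labels == 1].mean())
        if (~labels.astype(bool)).any():
            lo = float(values[labels == 0].mean())
    return labels


@dataclass
class BlockVarianceExplained:
    """Result of the two-step block variance-explained statistic."""

    value: float
    beta: float = float("nan")
    g2_haplotypes: tuple[int, ...] = ()
    degenerate: bool = False


def block_variance_explained(
    y: np.ndarray, block: HaplotypeBlock, sigma_p2: float
) -> BlockVarianceExplained:
    """Two-step fraction of phenotypic variance explained by a block.

    Step 1 clusters least-squares haplotype effects into two groups
    (G1/G2) by 1-D two-means; step 2 scores each animal 0/1/2 by its G2
    haplotype count from the EM diplotypes, regresses the phenotype on the
    score, and returns ``2 p q beta^2 / sigma_p2`` with ``p``/``q`` the
    G1/G2 frequency masses.
    """
    if block.hap_dosages is None or block.diplotypes is None:
        raise ValueError("block must be phased first (em_phase)")
    if sigma_p2 <= 0:
        raise ValueError("sigma_p2 must be positive")
    y = np.asarray(y, dtype=float)
    t = block.n_haplotypes
    if t < 2:
        return BlockVarianceExplained(0.0, degenerate=True)

    X = np.column_stack([np.ones(y.size), block.hap_dosages[:, 1:]])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    effects = np.concatenate([[0.0], coef[1:]])  # baseline haplotype at 0

    if np.ptp(effects) < 1e-12:
        return BlockVarianceExplained(0.0, degenerate=True)
    labels = _two_means_1d(effects)
    # G2 = the higher-effect group
    if effects[labels == 1].mean() < effects[labels == 0].mean():
        labels = 1 - labels
    g2 = np.flatnonzero(labels == 1)

    indicator = np.isin(block.diplotypes, g2).sum(axis=1).astype(float)
    if np.ptp(indicator) == 0:
        return BlockVarianceExplained(0.0, g2_haplotypes=tuple(g2), degenerate=True)
    x = indicator - indicator.mean()
    beta = float((x @ (y - y.mean())) / (x @ x))
    q = float(block.frequencies[labels == 1].sum())
    p = 1.0 - q
    value = float(np.clip(2.0 * p * q * beta**2 / sigma_p2, 0.0, 1.0))
    return BlockVarianceExplained(value, beta, tuple(int(i) for i in g2))


__all__ = [
    "LdStats",
    "HaplotypeBlock",
    "GabrielThresholds",
    "block_length",
    "pairwise_ld",
    "partition_blocks",
    "em_phase",
    "block_assoc",
    "block_variance_explained",
    "BlockVarianceExplained",
]
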