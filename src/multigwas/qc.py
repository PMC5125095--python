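"""Marker and sample quality control.

Default thresholds follow common BeadChip practice for cattle panels:
markers are dropped when call rate < 95%, MAF < 0.05 or the exact
Hardy-Weinberg test gives P < 1e-5; samples are dropped when more than 10%
of their calls are missing.  All comparisons are strict in the stated
direction, so a SNP with MAF exactly 0.05 or a sample missing exactly 10%
survives.

Missing calls are filled by per-SNP binomial draws at the observed allele
frequency.  This is a deliberately simple, seeded imputer: it preserves
allele frequencies and removes missingness but ignores LD, and is not an
accuracy-bearing step in any downstream test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 1e-5
    max_sample_missing: float = 0.10

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QcReport:
    removed: dict[str, int] = field(default_factory=dict)
    surviving_snps: list[str] = field(default_factory=list)
    surviving_samples: list[str] = field(default_factory=list)
    snp_stats: pd.DataFrame | None = None

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg P for one biallelic genotype table.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed
    one (the standard exact SNP-HWE formulation).  A monomorphic locus
    carries no information and returns P = 1.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")

    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # count of the rarer allele
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # probabilities over heterozygote counts of the same parity as n_rare,
    # via the standard ratio recurrence, normalized at the end
    het_max = min(n_rare, 2 * n - n_rare)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward from the mode: P(h-2)/P(h) = h(h-1) / ((r-h+2)(c-h+2))
    h = mid
    while h >= 2:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        nxt = probs[h] * h * (h - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
        h -= 2
        probs[h] = nxt
    # upward: P(h+2)/P(h) = 4 r c / ((h+2)(h+1))
    h = mid
    while h + 2 <= het_max:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        nxt = probs[h] * 4.0 * rare_hom * common_hom / ((h + 2) * (h + 1))
        h += 2
        probs[h] = nxt

    total = sum(probs.values())
    observed = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= observed * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    """Exact HWE P per SNP, computed on called genotypes only."""
    out = np.empty(G.n_snps)
    d = G.dosages
    for j in range(G.n_snps):
        col = d[:, j]
        called = col[col != MISSING]
        out[j] = hwe_exact_test(
            int(np.sum(called == 2)), int(np.sum(called == 1)), int(np.sum(called == 0))
        )
    return out


def snp_qc_filter(
    G: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs failing call-rate, MAF or HWE rules.

    All three statistics are computed on the input matrix once; rules are
    applied in the order call-rate -> MAF -> HWE so each removal is
    attributed to the first rule it trips.
    """
    if G.n_snps == 0:
        raise ValueError("empty genotype matrix")
    call_rate = G.call_rate()
    maf = G.maf()
    hwe_p = hwe_pvalues(G)

    fail_cr = call_rate < t.min_call_rate
    fail_maf = ~fail_cr & (maf < t.min_maf)
    fail_hwe = ~fail_cr & ~fail_maf & (hwe_p < t.hwe_alpha)
    keep = ~(fail_cr | fail_maf | fail_hwe)

    stats = pd.DataFrame(
        {
            "snp_id": G.snps["snp_id"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "kept": keep,
        }
    )
    report = QcReport(
        removed={
            "call_rate": int(fail_cr.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        },
        surviving_snps=G.snps.loc[keep, "snp_id"].tolist(),
        surviving_samples=list(G.samples),
        snp_stats=stats,
    )
    return G.take_snps(np.flatnonzero(keep)), report


def sample_qc_filter(
    G: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples whose missing-call fraction strictly exceeds the threshold."""
    miss = G.sample_missing_rate()
    keep = miss <= t.max_sample_missing
    if not keep.any():
        raise ValueError("sample QC would remove every sample")
    report = QcReport(
        removed={"sample_missing": int((~keep).sum())},
        surviving_snps=G.snps["snp_id"].tolist(),
        surviving_samples=[s for s, k in zip(G.samples, keep) if k],
    )
    return G.take_samples(np.flatnonzero(keep)), report


def run_qc(
    G: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """SNP rules first, then sample missingness; merged report."""
    G1, rep_snp = snp_qc_filter(G, t)
    G2, rep_sample = sample_qc_filter(G1, t)
    removed = dict(rep_snp.removed)
    removed.update(rep_sample.removed)
    return G2, QcReport(
        removed=removed,
        surviving_snps=rep_snp.surviving_snps,
        surviving_samples=rep_sample.surviving_samples,
        snp_stats=rep_snp.snp_stats,
    )


def impute_missing(G: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Fill missing dosages with Binomial(2, p-hat) draws per SNP."""
    mask = G.missing_mask
    if not mask.any():
        return G.copy()
    p = G.allele_freq()
    if np.isnan(p).any():
        bad = G.snps.loc[np.isnan(p), "snp_id"].tolist()
        raise ValueError(f"SNPs with zero observed calls cannot be imputed: {bad[:5]}")
    rng = np.random.default_rng(seed)
    dosages = G.dosages.copy()
    rows, cols = np.nonzero(mask)
    dosages[rows, cols] = rng.binomial(2, p[cols]).astype(np.int8)
    return GenotypeMatrix(dosages, list(G.samples), G.snps.copy())


__all__ = [
    "QcThresholds",
    "QcReport",
    "hwe_exact_test",
    "hwe_pvalues",
    "snp_qc_filter",
    "sample_qc_filter",
    "run_qc",
    "impute_missing",
]
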