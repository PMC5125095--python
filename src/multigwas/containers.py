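"""Core in-memory containers shared by all analysis strategies.

Genotypes are held as additive dosage codes (count of the ``a1`` allele,
0/1/2) in a samples x SNPs int8 array with ``-1`` marking missing calls.
SNP metadata travels alongside in a :class:`pandas.DataFrame` with columns
``snp_id, chrom, pos, a1, a2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]

PHENOTYPE_COLUMNS = ["sample_id", "adg", "sex", "birth_year", "calving_season"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with missingness mask.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` int8 array of ``a1``-allele counts;
        ``-1`` encodes a missing call.
    samples
        Sample identifiers, one per row.
    snps
        Per-SNP metadata frame with columns ``snp_id, chrom, pos, a1, a2``.
    """

    dosages: np.ndarray
    samples: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        self.samples = list(self.samples)
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample list does not match dosage rows")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps frame lacks columns {missing_cols}")
        if len(self.snps) != self.dosages.shape[1]:
            raise ValueError("snp frame does not match dosage columns")
        bad = (self.dosages < -1) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing calls."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        """Per-sample fraction of missing calls."""
        return self.missing_mask.mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted (``a1``) allele among called genotypes."""
        d = self.dosages.astype(float)
        d[self.missing_mask] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with missing entries set to NaN."""
        d = self.dosages.astype(float)
        d[self.missing_mask] = np.nan
        return d

    def take_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype != bool:
            index = index.astype(int)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.samples,
            self.snps.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        else:
            index = index.astype(int)
        return GenotypeMatrix(
            self.dosages[index],
            [self.samples[i] for i in index],
            self.snps.copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), list(self.samples), self.snps.copy())


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix over samples."""

    values: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if n != m:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def check_psd(self, tol: float = 1e-8) -> None:
        lo = self.min_eigenvalue()
        scale = max(1.0, float(np.abs(self.values).max()))
        if lo < -tol * scale:
            raise ValueError(f"kinship not PSD: min eigenvalue {lo:.3g}")


@dataclass
class VarianceComponents:
    """REML additive / residual variance estimates for the single-kinship MLM."""

    sigma_a2: float
    sigma_e2: float
    h2: float
    loglik: float
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")


@dataclass
class AssocResult:
    """Unified association record for SNP-, block- and gene-level tests."""

    test_id: str
    beta: float
    se: float
    chi2: float
    p: float
    var_explained: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of (0, 1]: {self.p}")


def results_to_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Flatten association records to a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "id": [r.test_id for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "var_explained": [r.var_explained for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


__all__ = [
    "MISSING",
    "SNP_COLUMNS",
    "PHENOTYPE_COLUMNS",
    "GenotypeMatrix",
    "KinshipMatrix",
    "VarianceComponents",
    "AssocResult",
    "results_to_frame",
    "replace",
]
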