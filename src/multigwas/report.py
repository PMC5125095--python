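"""Cross-strategy integration and the expression follow-up.

Collates the SNP-, haplotype- and gene-level hits into Venn-style SNP
sets, colors regional SNPs by their maximum r2 against the lead markers,
exports Manhattan-ready tables, and tests whether qPCR transcript
abundance (2^-ddCt fold change) associates with the growth trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import AssocResult, GenotypeMatrix
from .hapblock import pairwise_ld


@dataclass
class SignificantSets:
    """The seven Venn regions over SNP ids from the three strategies."""

    snp_only: set[str]
    block_only: set[str]
    gene_only: set[str]
    snp_block: set[str]
    snp_gene: set[str]
    block_gene: set[str]
    all_three: set[str]

    @property
    def union_size(self) -> int:
        return sum(
            len(s)
            for s in (
                self.snp_only, self.block_only, self.gene_only,
                self.snp_block, self.snp_gene, self.block_gene, self.all_three,
            )
        )

    def counts(self) -> dict[str, int]:
        return {
            "snp_only": len(self.snp_only),
            "block_only": len(self.block_only),
            "gene_only": len(self.gene_only),
            "snp_block": len(self.snp_block),
            "snp_gene": len(self.snp_gene),
            "block_gene": len(self.block_gene),
            "all_three": len(self.all_three),
            "union": self.union_size,
        }


def intersect_significant_sets(
    snp_sig: Iterable[str],
    block_sig: Iterable[str],
    gene_sig: Iterable[str],
    universe: Iterable[str] | None = None,
) -> SignificantSets:
    """Venn decomposition of the three strategies' significant SNP sets.

    Block- and gene-level hits must already be expanded to their member
    SNP ids.  When ``universe`` is given, any id outside it raises (guards
    against mixing marker namespaces).
    """
    A, B, C = set(snp_sig), set(block_sig), set(gene_sig)
    if universe is not None:
        uni = set(universe)
        stray = (A | B | C) - uni
        if stray:
            raise ValueError(f"ids outside the SNP namespace: {sorted(stray)[:5]}")
    return SignificantSets(
        snp_only=A - B - C,
        block_only=B - A - C,
        gene_only=C - A - B,
        snp_block=(A & B) - C,
        snp_gene=(A & C) - B,
        block_gene=(B & C) - A,
        all_three=A & B & C,
    )


def expand_block_snps(blocks: Sequence) -> set[str]:
    """Member SNP ids of significant blocks (or gene windows)."""
    out: set[str] = set()
    for b in blocks:
        out.update(b.snp_ids)
    return out


LD_CLASSES = (
    (0.9, "r2>0.9"),
    (0.7, "r2>0.7"),
    (0.5, "r2>0.5"),
    (0.3, "r2>0.3"),
    (-np.inf, "r2<0.3"),
)


def regional_ld_classes(
    G: GenotypeMatrix,
    lead_snp_ids: Sequence[str],
    region: tuple[str, int, int],
) -> pd.DataFrame:
    """Color class of each region SNP by max r2 against the lead SNPs.

    Classes follow the strict-inequality bins >0.9, >0.7, >0.5, >0.3 and
    <0.3 (a boundary value falls to the lower class).
    """
    chrom, start, end = region
    ids = G.snps["snp_id"].astype(str)
    lead_idx = [int(i) for i in np.flatnonzero(ids.isin(list(lead_snp_ids)))]
    if len(lead_idx) != len(set(lead_snp_ids)):
        raise ValueError("some lead SNPs are absent from the genotype matrix")
    sel = np.flatnonzero(
        (G.snps["chrom"].astype(str) == str(chrom))
        & (G.snps["pos"] >= start)
        & (G.snps["pos"] <= end)
    )
    rows = []
    for j in sel:
        best = 0.0
        for li in lead_idx:
            if li == j:
                best = 1.0
                break
            ld = pairwise_ld(G.dosages[:, li], G.dosages[:, j])
            if ld.defined and ld.r2 > best:
                best = ld.r2
        label = next(lab for thr, lab in LD_CLASSES if best > thr)
        rows.append((ids.iloc[j], int(G.snps["pos"].iloc[j]), best, label))
    return pd.DataFrame(rows, columns=["snp_id", "pos", "max_r2", "ld_class"])


def fold_change_ddct(
    ct_target: float, ct_ref: float, calibrator_dct: float
) -> float:
    """Relative expression by the 2^-ddCt method.

    ``dCt = Ct_target - Ct_reference`` (reference = internal-control
    gene); ``ddCt`` subtracts the calibrator's dCt; the fold change is
    ``2**(-ddCt)``.
    """
    for v in (ct_target, ct_ref, calibrator_dct):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_ref) - calibrator_dct
    return float(2.0 ** (-ddct))


def expression_assoc(
    adg: np.ndarray,
    fold_change: np.ndarray,
    covariates: pd.DataFrame | None = None,
    test_id: str = "expression",
) -> AssocResult:
    """OLS of the trait on transcript fold change plus fixed covariates.

    Reports the slope in trait units per unit fold change, its standard
    error and the Wald P-value.
    """
    adg = np.asarray(adg, dtype=float)
    fc = np.asarray(fold_change, dtype=float)
    cols = {"fold_change": fc}
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True)
                for c in dummies.columns:
                    cols[c] = dummies[c].to_numpy(dtype=float)
            else:
                cols[name] = col.to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    if adg.size < X.shape[1] + 2:
        raise ValueError("too few samples for the covariate-adjusted regression")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name the offending columns for the caller
        bad = []
        base = Xc.to_numpy()
        for k, name in enumerate(Xc.columns):
            others = np.delete(base, k, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(str(name))
        raise ValueError(f"collinear design; suspect columns: {bad}")
    fit = sm.OLS(adg, Xc).fit()
    beta = float(fit.params["fold_change"])
    se = float(fit.bse["fold_change"])
    p = float(fit.pvalues["fold_change"])
    p = max(p, 5e-324)
    chi2 = (beta / se) ** 2 if se > 0 else float("inf")
    return AssocResult(test_id, beta, se, chi2, p)


def manhattan_export(
    results: pd.DataFrame,
    threshold: float = 1e-6,
    chrom_col: str = "chrom",
    pos_col: str = "pos",
    p_col: str = "p",
) -> pd.DataFrame:
    """Plot-ready table: cumulative position and -log10 P per marker.

    Chromosomes are laid end to end in natural sort order; any plotting
    front-end can consume the output.
    """
    if results.empty:
        raise ValueError("no results to export")
    df = results.copy()
    df[chrom_col] = df[chrom_col].astype(str)

    def _key(c: str):
        c = c.removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    chrom_order = sorted(df[chrom_col].unique(), key=_key)
    offset = 0
    offsets = {}
    for ch in chrom_order:
        offsets[ch] = offset
        offset += int(df.loc[df[chrom_col] == ch, pos_col].max()) + 1
    df["cum_pos"] = df[pos_col] + df[chrom_col].map(offsets)
    df["neg_log10_p"] = -np.log10(df[p_col])
    df["significant"] = df[p_col] < threshold
    df = df.sort_values(["cum_pos"], kind="stable").reset_index(drop=True)
    return df


__all__ = [
    "SignificantSets",
    "intersect_significant_sets",
    "expand_block_snps",
    "regional_ld_classes",
    "fold_change_ddct",
    "expression_assoc",
    "manhattan_export",
    "LD_CLASSES",
]
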