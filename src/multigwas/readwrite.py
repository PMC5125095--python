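"""Genotype I/O: PLINK 1.x bed/bim/fam triples and VCF v4.2.

The bed codec follows the PLINK 1.x binary spec (SNP-major, two bits per
call, four calls per byte, least-significant bits first): ``00`` hom A1,
``10`` het, ``11`` hom A2, ``01`` missing.  Dosages here count the A1
allele, so ``00 -> 2``, ``10 -> 1``, ``11 -> 0``.  VCF is written as plain
text with the A2 allele as REF and A1 as ALT (dosage = ALT count) and read
back through cyvcf2.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, SNP_COLUMNS, GenotypeMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix: str | Path, ext: str) -> Path:
    prefix = Path(prefix)
    return prefix.parent / f"{prefix.name}.{ext}"

# dosage of A1 -> 2-bit code
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam triple; round-trips dosages, missingness and metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = G.n_samples

    codes = np.empty_like(G.dosages, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[G.dosages == dosage] = code

    n_bytes = (n + 3) // 4
    padded = np.zeros((n_bytes * 4, max(G.n_snps, 1)), dtype=np.uint8)
    if G.n_snps:
        padded[:n] = codes
    by = (
        padded[0::4]
        | (padded[1::4] << 2)
        | (padded[2::4] << 4)
        | (padded[3::4] << 6)
    )
    with open(_ext(prefix, "bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        if G.n_snps:
            fh.write(by.T.tobytes())  # SNP-major

    bim = pd.DataFrame(
        {
            "chrom": G.snps["chrom"],
            "snp_id": G.snps["snp_id"],
            "cm": 0,
            "pos": G.snps["pos"],
            "a1": G.snps["a1"],
            "a2": G.snps["a2"],
        }
    )
    bim.to_csv(_ext(prefix, "bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": G.samples,
            "iid": G.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(_ext(prefix, "fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    fam = pd.read_csv(
        _ext(prefix, "fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    try:
        bim = pd.read_csv(
            _ext(prefix, "bim"),
            sep=r"\s+",
            header=None,
            names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
        )
    except pd.errors.EmptyDataError:
        bim = pd.DataFrame(columns=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
    n, m = len(fam), len(bim)

    raw = np.fromfile(_ext(prefix, "bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1.x bed file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if m and body.size != m * n_bytes:
        raise ValueError(f"{prefix}.bed: unexpected size")
    dosages = np.empty((n, m), dtype=np.int8)
    if m:
        by = body.reshape(m, n_bytes)
        codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
        codes[:, 0::4] = by & 0b11
        codes[:, 1::4] = (by >> 2) & 0b11
        codes[:, 2::4] = (by >> 4) & 0b11
        codes[:, 3::4] = (by >> 6) & 0b11
        dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    snps = pd.DataFrame(
        {
            "snp_id": bim["snp_id"].astype(str),
            "chrom": bim["chrom"].astype(str),
            "pos": bim["pos"].astype(int) if m else bim["pos"],
            "a1": bim["a1"].astype(str),
            "a2": bim["a2"].astype(str),
        },
        columns=SNP_COLUMNS,
    )
    return GenotypeMatrix(dosages, fam["iid"].astype(str).tolist(), snps)


_GT_STRING = {2: "1/1", 1: "0/1", 0: "0/0", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write uncompressed VCF v4.2 with GT only; REF = A2, ALT = A1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + G.samples) + "\n")
        for j in range(G.n_snps):
            row = G.snps.iloc[j]
            gts = "\t".join(_GT_STRING[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.a2}\t{row.a1}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    for var in vcf:
        # gt_types: 0 HOM_REF, 1 HET, 3 HOM_ALT, 2 UNKNOWN
        gt = np.asarray(var.gt_types)
        d = np.full(gt.shape, MISSING, dtype=np.int8)
        d[gt == 0] = 0
        d[gt == 1] = 1
        d[gt == 3] = 2
        rows.append(d)
        alt = var.ALT[0] if var.ALT else "."
        meta.append((var.ID or ".", str(var.CHROM), int(var.POS), alt, var.REF))
    vcf.close()
    if rows:
        dosages = np.stack(rows, axis=1)
    else:
        dosages = np.empty((len(samples), 0), dtype=np.int8)
    snps = pd.DataFrame(meta, columns=SNP_COLUMNS)
    return GenotypeMatrix(dosages, samples, snps)


def write_genotypes(G: GenotypeMatrix, path: str | Path, format: str = "plink") -> None:
    """Dispatch on ``format`` in {'plink', 'vcf'}."""
    if format == "plink":
        write_plink(G, path)
    elif format == "vcf":
        write_vcf(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_genotypes(path: str | Path, format: str = "plink") -> GenotypeMatrix:
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
]
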