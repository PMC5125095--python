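"""Synthetic genotype/phenotype generator with known ground truth.

The generator emulates a beef-cattle growth-trait study design: ~1,000
animals genotyped on an LD-block-structured SNP panel (MAF >= 0.05), an
additive trait (average daily gain) with mean 0.98 kg/day, SD 0.16 kg/day
and narrow-sense heritability 0.48, categorical fixed effects (sex, birth
year, calving season), and optional planted causal SNPs / haplotypes.

Within-block LD arises solely from a finite founder-haplotype pool built on
a perfect phylogeny (each SNP mutates once on the founder tree), so every
within-block pair of SNPs has |D'| = 1 while distinct blocks are simulated
in linkage equilibrium.  This gives the block partitioner and the phaser an
exact ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, SNP_COLUMNS, GenotypeMatrix

_RESAMPLE_LIMIT = 500


@dataclass(frozen=True)
class CausalEffect:
    """A planted additive effect.

    ``kind='snp'`` plants an effect of ``beta`` (trait units per allele) on
    SNP ``index`` of block ``block``; ``kind='haplotype'`` plants ``beta``
    per copy of founder haplotype ``index`` of block ``block``.  A
    gene-level multi-SNP effect is expressed as several SNP entries within
    one block.
    """

    kind: str
    block: int
    index: int
    beta: float

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "haplotype"):
            raise ValueError(f"unknown causal kind {self.kind!r}")


@dataclass(frozen=True)
class FixedEffect:
    """A categorical covariate with one additive effect per level (trait units)."""

    name: str
    effects: tuple[float, ...]

    @property
    def n_levels(self) -> int:
        return len(self.effects)


def default_fixed_effects() -> tuple[FixedEffect, ...]:
    # Sex, birth year and calving season at study-like level counts with
    # modest effects (a few percent of a trait SD each).
    return (
        FixedEffect("sex", (0.0, 0.01)),
        FixedEffect("birth_year", (0.0, 0.005, -0.005, 0.01, -0.01, 0.0)),
        FixedEffect("calving_season", (0.0, 0.008, -0.008, 0.0)),
    )


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset."""

    n_samples: int = 1000
    n_blocks: int = 40
    snps_per_block: int = 5
    block_span_bp: int = 20_000
    block_gap_bp: int = 200_000
    founder_haplotypes_per_block: int = 4
    maf_min: float = 0.05
    heritability_target: float = 0.48
    trait_mean: float = 0.98
    trait_sd: float = 0.16
    causal_spec: tuple[CausalEffect, ...] = ()
    fixed_effects: tuple[FixedEffect, ...] = field(default_factory=default_fixed_effects)
    missing_rate: float = 0.0
    n_chromosomes: int = 1
    seed: int = 0
    founder_pools: list[np.ndarray] | None = None
    founder_freqs: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.snps_per_block < 2:
            raise ValueError("snps_per_block must be >= 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0.0 < self.heritability_target < 1.0:
            raise ValueError("heritability_target must lie in (0, 1)")
        for name, frac in (
            ("maf_min", self.maf_min),
            ("missing_rate", self.missing_rate),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        if self.founder_haplotypes_per_block < 2 and self.founder_pools is None:
            raise ValueError("founder pool must contain at least 2 haplotypes")


@dataclass
class SimTruth:
    """Ground-truth labels emitted alongside the simulated data."""

    founder_pools: list[np.ndarray]
    founder_freqs: list[np.ndarray]
    hap_indices: np.ndarray  # (n_samples, n_blocks, 2) founder index per chromosome copy
    block_bounds: pd.DataFrame  # chrom, start, end, first_snp, n_snps per block
    snp_block: np.ndarray  # block index of each SNP
    true_dosages: np.ndarray | None = None  # pre-masking dosage matrix
    causal: tuple[CausalEffect, ...] = ()
    sigma_a2: float = float("nan")
    sigma_e2: float = float("nan")
    polygenic_values: np.ndarray | None = None
    causal_values: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def phased_haplotypes(self, block: int) -> np.ndarray:
        """(n_samples, 2, snps) phased alleles for one block."""
        pool = self.founder_pools[block]
        idx = self.hap_indices[:, block, :]
        return pool[idx]

    def unphase(self) -> np.ndarray:
        """Collapse the phased truth back to an unphased dosage matrix."""
        parts = []
        for b in range(len(self.founder_pools)):
            h = self.phased_haplotypes(b)
            parts.append(h.sum(axis=1))
        return np.concatenate(parts, axis=1).astype(np.int8)


def _perfect_phylogeny_pool(
    rng: np.random.Generator, n_founders: int, n_snps: int
) -> np.ndarray:
    """Founder haplotypes on a random perfect phylogeny.

    Founder 0 is all-ancestral; each later founder copies a random earlier
    founder and carries the derived allele at the SNPs assigned to its
    branch.  Every SNP mutates exactly once, so all pairwise |D'| = 1.
    """
    pool = np.zeros((n_founders, n_snps), dtype=np.int8)
    # every branch event gets at least one SNP when possible
    events = np.arange(1, n_founders)
    assignment = np.empty(n_snps, dtype=int)
    k = min(n_snps, len(events))
    assignment[:k] = rng.permutation(events)[:k]
    if n_snps > k:
        assignment[k:] = rng.choice(events, size=n_snps - k)
    for j in range(1, n_founders):
        parent = int(rng.integers(0, j))
        pool[j] = pool[parent]
        pool[j, assignment == j] = 1
    return pool


def _draw_block_pool(
    rng: np.random.Generator,
    config: SimConfig,
    block: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Founder pool + frequencies satisfying the expected-MAF floor."""
    fixed_freqs = None
    if config.founder_freqs is not None and config.founder_freqs[block] is not None:
        fixed_freqs = np.asarray(config.founder_freqs[block], dtype=float)
        if abs(fixed_freqs.sum() - 1.0) > 1e-8:
            raise ValueError(f"block {block}: founder frequencies must sum to 1")

    if config.founder_pools is not None:
        pool = np.asarray(config.founder_pools[block], dtype=np.int8)
        if pool.shape[0] < 2:
            raise ValueError(f"block {block}: founder pool must hold >= 2 haplotypes")
        freqs = (
            fixed_freqs
            if fixed_freqs is not None
            else np.full(pool.shape[0], 1.0 / pool.shape[0])
        )
        return pool, freqs

    n_f = config.founder_haplotypes_per_block
    pool = _perfect_phylogeny_pool(rng, n_f, config.snps_per_block)
    for attempt in range(_RESAMPLE_LIMIT):
        freqs = fixed_freqs if fixed_freqs is not None else rng.dirichlet(np.ones(n_f))
        p = freqs @ pool  # expected derived-allele frequency per SNP
        if np.all(np.minimum(p, 1 - p) >= config.maf_min):
            return pool, freqs
        if fixed_freqs is not None or (attempt + 1) % 25 == 0:
            pool = _perfect_phylogeny_pool(rng, n_f, config.snps_per_block)
    raise RuntimeError(
        f"block {block}: could not satisfy MAF >= {config.maf_min} "
        f"after {_RESAMPLE_LIMIT} frequency draws"
    )


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw an LD-block-structured genotype panel plus its phased truth.

    Each sample's genotype at a block is the sum of two founder haplotypes
    drawn independently (random mating) from that block's pool; blocks are
    mutually in linkage equilibrium.  Missing calls are masked completely
    at random at ``config.missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n, n_blocks = config.n_samples, config.n_blocks

    pools: list[np.ndarray] = []
    freqs: list[np.ndarray] = []
    dosage_parts: list[np.ndarray] = []
    hap_idx = np.empty((n, n_blocks, 2), dtype=np.int32)
    for b in range(n_blocks):
        pool, fr = _draw_block_pool(rng, config, b)
        pools.append(pool)
        freqs.append(fr)
        draws = rng.choice(pool.shape[0], size=(n, 2), p=fr)
        hap_idx[:, b, :] = draws
        dosage_parts.append((pool[draws[:, 0]] + pool[draws[:, 1]]).astype(np.int8))

    true_dosages = np.concatenate(dosage_parts, axis=1)
    n_snps = true_dosages.shape[1]

    # genomic coordinates: blocks laid end to end with a recombination gap,
    # split contiguously over chromosomes
    per_chrom = math.ceil(n_blocks / config.n_chromosomes)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    bounds = []
    snp_block = np.empty(n_snps, dtype=int)
    cursor = 0
    for b in range(n_blocks):
        chrom = str(b // per_chrom + 1)
        within = b % per_chrom
        start = 1 + within * (config.block_span_bp + config.block_gap_bp)
        pos = np.sort(
            rng.choice(
                np.arange(start, start + config.block_span_bp),
                size=config.snps_per_block,
                replace=False,
            )
        )
        positions.append(pos)
        chroms.extend([chrom] * config.snps_per_block)
        bounds.append(
            {
                "block": b,
                "chrom": chrom,
                "start": int(pos[0]),
                "end": int(pos[-1]),
                "first_snp": cursor,
                "n_snps": config.snps_per_block,
            }
        )
        snp_block[cursor : cursor + config.snps_per_block] = b
        cursor += config.snps_per_block

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(n_snps)],
            "chrom": chroms,
            "pos": np.concatenate(positions),
            "a1": "A",
            "a2": "G",
        },
        columns=SNP_COLUMNS,
    )

    dosages = true_dosages.copy()
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    G = GenotypeMatrix(dosages, [f"id{i:05d}" for i in range(n)], snps)
    truth = SimTruth(
        founder_pools=pools,
        founder_freqs=freqs,
        hap_indices=hap_idx,
        block_bounds=pd.DataFrame(bounds),
        snp_block=snp_block,
        true_dosages=true_dosages,
        causal=tuple(config.causal_spec),
    )
    return G, truth


def vanraden_kinship(dosages: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from a complete dosage matrix."""
    p = dosages.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    Z = dosages[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    if denom <= 0:
        raise ValueError("no polymorphic SNPs for kinship")
    return (Z @ Z.T) / denom


def _causal_values(truth: SimTruth, causal: tuple[CausalEffect, ...]) -> np.ndarray:
    n = truth.hap_indices.shape[0]
    c = np.zeros(n)
    for eff in causal:
        if eff.kind == "snp":
            first = int(truth.block_bounds.loc[eff.block, "first_snp"])
            x = truth.true_dosages[:, first + eff.index].astype(float)
        else:
            idx = truth.hap_indices[:, eff.block, :]
            x = (idx == eff.index).sum(axis=1).astype(float)
        c += eff.beta * x
    return c


def simulate_phenotype(
    G: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """Simulate the trait: y = mu + Wv + sum_k x_k b_k + u + e.

    The polygenic term ``u`` is drawn with covariance ``sigma_a2 * K_true``
    where ``K_true`` is the VanRaden matrix over all simulated SNPs, so the
    estimation model used downstream is exactly the generating model.
    Variances are scaled so that narrow-sense heritability (causal +
    polygenic over genetic + residual) equals ``heritability_target``; when
    the planted causal variance alone exceeds the target genetic variance,
    the heritability target takes precedence and the total SD inflates
    above ``trait_sd``.
    """
    if G.n_samples != truth.hap_indices.shape[0]:
        raise ValueError("genotypes and truth cover different samples")
    if not 0.0 < config.heritability_target < 1.0:
        raise ValueError("heritability_target must lie in (0, 1)")
    rng = np.random.default_rng([config.seed, 1])
    n = G.n_samples
    h2 = config.heritability_target

    # categorical fixed effects
    cov = {}
    wv = np.zeros(n)
    for fe in config.fixed_effects:
        levels = rng.integers(0, fe.n_levels, size=n)
        cov[fe.name] = levels
        wv += np.asarray(fe.effects)[levels]
    var_fixed = float(np.var(wv))

    c = _causal_values(truth, tuple(config.causal_spec))
    var_c = float(np.var(c))

    sigma_p2 = config.trait_sd**2 - var_fixed
    if sigma_p2 <= 0:
        raise ValueError("fixed-effect variance exceeds trait variance target")
    if var_c <= h2 * sigma_p2:
        sigma_a2 = h2 * sigma_p2 - var_c
        sigma_e2 = (1.0 - h2) * sigma_p2
    else:
        sigma_a2 = 0.0
        sigma_e2 = var_c * (1.0 - h2) / h2

    K = vanraden_kinship(truth.true_dosages.astype(float))
    if sigma_a2 > 0:
        L = np.linalg.cholesky(sigma_a2 * K + 1e-9 * np.eye(n))
        u = L @ rng.standard_normal(n)
    else:
        u = np.zeros(n)
    e = rng.normal(0.0, math.sqrt(sigma_e2), size=n)

    y = config.trait_mean + (wv - wv.mean()) + (c - c.mean()) + u + e

    truth.sigma_a2 = sigma_a2
    truth.sigma_e2 = sigma_e2
    truth.polygenic_values = u
    truth.causal_values = c
    truth.covariates = pd.DataFrame(cov)

    pheno = pd.DataFrame({"sample_id": G.samples, "adg": y})
    for name in ("sex", "birth_year", "calving_season"):
        pheno[name] = cov.get(name, np.zeros(n, dtype=int))
    return pheno


@dataclass(frozen=True)
class WeightRecord:
    """One weighing of one animal."""

    sample_id: str
    age_days: float
    weight_kg: float


def adg_from_weights(records: list[WeightRecord]) -> float:
    """Average daily gain: OLS slope of weight (kg) on age (days).

    The growth curve over the fattening period is close to linear, so the
    regression slope is the gain per day.
    """
    if len(records) < 2:
        raise ValueError("need at least two weighings")
    ages = np.array([r.age_days for r in records], dtype=float)
    weights = np.array([r.weight_kg for r in records], dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("all ages identical; slope undefined")
    x = ages - ages.mean()
    return float((x @ (weights - weights.mean())) / (x @ x))


def simulate_weight_records(
    pheno: pd.DataFrame,
    config: SimConfig,
    ages_days: tuple[float, ...] = (0.0, 240.0, 365.0, 548.0, 700.0),
    fattening_window: tuple[float, float] = (240.0, 700.0),
    weight_noise_kg: float = 2.0,
    birth_weight_kg: float = 40.0,
) -> dict[str, list[WeightRecord]]:
    """Raw weighings whose fattening-window regression slope recovers ADG.

    Five weighings per animal by default (birth, entry to the fattening
    farm, 12 months, 18 months, slaughter); the window over which the slope
    is taken is exposed as a parameter because growth is only linear during
    fattening.
    """
    lo, hi = fattening_window
    if sum(lo <= a <= hi for a in ages_days) < 2:
        raise ValueError("fattening window must contain >= 2 weighings")
    rng = np.random.default_rng([config.seed, 2])
    out: dict[str, list[WeightRecord]] = {}
    entry = min(a for a in ages_days if a >= lo)
    for sid, adg in zip(pheno["sample_id"], pheno["adg"]):
        recs = []
        # pre-fattening growth at a slower, juvenile rate
        juvenile_rate = 0.7 * adg
        entry_weight = birth_weight_kg + juvenile_rate * entry
        for a in sorted(ages_days):
            if a < lo:
                w = birth_weight_kg + juvenile_rate * a
            else:
                w = entry_weight + adg * (a - entry)
            w += rng.normal(0.0, weight_noise_kg)
            recs.append(WeightRecord(sid, a, w))
        out[sid] = recs
    return out


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


__all__ = [
    "CausalEffect",
    "FixedEffect",
    "SimConfig",
    "SimTruth",
    "WeightRecord",
    "default_fixed_effects",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_weight_records",
    "adg_from_weights",
    "vanraden_kinship",
    "write_phenotypes",
    "read_phenotypes",
]
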