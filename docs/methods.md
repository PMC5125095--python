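# Methods

`multigwas` implements three complementary genome-wide association
strategies for a quantitative trait — here average daily gain (ADG) in
beef cattle, the slope of body weight (kg) on age (days) over the
fattening period — around one shared mixed linear model, together with a
synthetic-data generator that provides ground truth for every stage.

## The shared mixed model

All three strategies condition on the model

    y = W v + X b + u + e,      u ~ N(0, σ²_a K),   e ~ N(0, σ²_e I)

where `y` is the trait vector, `W` the fixed-effect design (intercept,
dummy-coded sex, birth year and calving season, and optionally the top
genotype principal components as population-stratification axes), `X b`
the tested term (a SNP dosage, a haplotype-dosage design, or absent), and
`K` a VanRaden genomic relationship matrix built from a seeded random
draw of autosomal SNPs (default cap 50,000): dosages centered by twice
the allele frequency and the cross-product scaled by `Σ 2p(1−p)`.

Variance components are estimated by single-kinship REML. The problem is
profiled to one dimension in the ratio `δ = σ²_e/σ²_a`: the data are
projected onto an explicit orthonormal complement of the fixed-effect
column space, rotated by the eigenvectors of the projected kinship, and
the restricted likelihood is maximized over a 121-point log-grid on
`δ ∈ [10⁻⁶, 10⁶]` followed by bounded scalar refinement (absolute
tolerance 1e-10 on log δ). The explicit complement basis matters: when
`K` has low rank (few markers), a naive eigendecomposition of the
projected kinship can leak fixed-effect directions — including the
intercept — into the rotated data and drive the residual variance toward
the trait's second moment. A boundary optimum is returned with a warning
flag rather than an error, and a kinship numerically proportional to the
identity triggers an unidentifiability warning (the ratio is then not
estimable). Heritability is reported as `σ²_a / (σ²_a + σ²_e)`.

The SNP scan uses the P3D/EMMAX approximation: variance components are
estimated once under the null and held fixed; each SNP is then tested by
GLS on whitened data, with the Wald statistic `(β̂/se)²` referred to
χ²(1). The standard error carries the residual mean square of the
whitened regression, which absorbs small misestimation of the global
variance ratio and keeps the null calibrated (measured type-I error at
α = 0.05 is within ±0.01 on null panels of 5,000 SNPs at n = 500). Exact
per-SNP REML is available behind `exact=True` for small panels.
Per-marker variance explained is `2pq β̂²/σ²_p`, clipped to [0, 1].

## Haplotype-block strategy

Pairwise LD is computed from 2-SNP EM haplotype frequencies (only the
double heterozygote is phase-ambiguous); D′ confidence intervals come
from a likelihood profile over a 101-point |D′| grid, normalized as a
posterior under a flat prior with the 5th/95th percentiles as bounds.
Blocks are delimited by the Gabriel CI rule with the PLINK 1.7 defaults
the method was designed around: a pair is strong LD when CI ∈
[lower ≥ 0.70, upper ≥ 0.98], strong recombination when the upper bound
is below 0.90; a span whose bounding pair is strong LD and whose
informative pairs are ≥ 95% strong LD is a candidate; longest candidates
win, blocks never overlap, and no block exceeds the 100 kb window.
Block length is reported as `end − start` in bp.

Within a block, haplotypes are inferred by a standard EM over all
haplotype pairs compatible with each genotype vector (enumeration bound
25 SNPs, configurable; convergence when the largest frequency change
falls below 1e-6, at most 1,000 sweeps; haplotypes below frequency 1e-4
pruned and frequencies renormalized, except where a genotype strictly
requires a rare haplotype). The association design uses expected
haplotype counts (posterior dosages), which is robust to residual phase
uncertainty; best-guess diplotypes are available as an option. The most
frequent haplotype is the baseline. The block statistic is the Wald
χ²(1) of the largest-magnitude haplotype effect under the global
variance components. Because the largest of t−1 effects is selected, the
1-df reference is conservative in the far tail for multi-haplotype
blocks; this mirrors the published test definition and is verified to
still spread P over (0, 1] under the null.

Variance explained by a block uses a two-step statistic: least-squares
haplotype effects are clustered into two groups by deterministic 1-D
two-means (centers initialized at the extreme effects); each animal is
scored 0/1/2 by its count of higher-group (G2) haplotypes from the EM
diplotypes; the score is regressed on the trait and `2pq β̂²/σ²_p` is
reported with p/q the G1/G2 frequency masses. For a two-haplotype block
this reduces exactly to the single-marker formula.

## Gene-based strategy

Gene windows are annotation intervals (BED 0-based half-open or GFF3
1-based closed, both normalized to 1-based closed) extended by ±50 kb,
clipped at 1; genes on non-autosomes or covered by fewer than three SNPs
are dropped with logged counts. Each window is summarized by the
principal components of its column-centered (unstandardized, by default)
dosage submatrix, keeping the smallest leading set whose cumulative
explained variance strictly exceeds 0.85; PC signs are fixed by making
each loading vector's largest-magnitude element positive so results are
machine-independent.

The phenotype entering the per-gene regressions is the GBLUP estimated
breeding value `û = σ²_a K V⁻¹(y − W v̂)` (verified against a dense
Henderson mixed-model-equation solve). Each PC is tested by simple
regression of the EBV on the score with a χ²(1) Wald statistic; the gene
P-value is the minimum over its retained PCs (with one PC it is that
PC's P; the min rule is applied uniformly for m ≥ 2). Genome-wide
significance comes from permutation: each cycle permutes the EBV across
samples — genotypes, and hence PC scores and per-gene LD, stay fixed —
and recomputes every gene's min-P; all `n_perm × n_genes` minima are
pooled and the cutoff is the `⌈α·N⌉`-th smallest (238,560 at the full
study dimensions of 23,856 genes × 1,000 cycles = 23,856,000 pooled
statistics). Permuting the raw trait and refitting GBLUP per cycle is
available behind the same interface by passing a recomputed EBV, but the
label-permutation null is the default for cost. Benjamini–Hochberg
q-values accompany the raw minima.

## Synthetic data generator

The generator emulates the study design the analyses assume, and its
defaults are the study conditions: ~1,000 samples, an LD-block panel
with MAF ≥ 0.05, trait mean 0.98 kg/day, SD 0.16 kg/day, heritability
0.48, and sex/birth-year/calving-season fixed effects with small
realistic level effects (≤ ~6% of a trait SD).

Within-block LD comes from a finite founder-haplotype pool built on a
random perfect phylogeny: each SNP mutates exactly once on the founder
tree, so every within-block pair has |D′| = 1 while r² varies with the
founder frequencies — the regime the Gabriel partitioner is designed to
segment. Founder frequencies are Dirichlet(1) draws resampled (up to 500
times, then an error naming the block) until every SNP's expected MAF
clears the floor; explicit pools and frequencies can be supplied to pin
particular structures (e.g. a causal haplotype at frequency 0.06).
Blocks are mutually in linkage equilibrium, separated by a configurable
gap (default 200 kb, beyond the partitioning window), which gives the
partitioner an unambiguous ground truth. Missingness is
missing-completely-at-random.

Phenotypes follow the estimation model exactly: the polygenic term is
drawn with covariance `σ²_a K_true` where `K_true` is the VanRaden
matrix over all simulated SNPs, so REML recovery tests are well-posed.
Variances are scaled so that narrow-sense heritability — (causal +
polygenic) over (genetic + residual) — equals the target and the total
SD matches the target; when a planted causal effect alone exceeds the
target genetic variance (the published strongest-haplotype regime,
0.45 kg/day at frequency 0.06, is such a case), the heritability target
takes precedence and the total SD inflates. Raw weight records emulate
five weighings (birth, feedlot entry, 12 and 18 months, slaughter) with
a slower juvenile growth rate before the fattening window; the window
over which the ADG regression is taken is a parameter because the
growth curve is linear only during fattening.

What the generator does *not* emulate: genotyping error, imputation
uncertainty structure, pedigree/family stratification, selection, sex
chromosomes, or LD between blocks. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions and
recoverability of planted structure — not robustness to real-data
artifacts beyond those assumptions.

## Quality control and imputation

Markers are dropped for call rate < 0.95, MAF < 0.05 or exact
Hardy–Weinberg P < 1e-5 (all statistics computed once on called
genotypes; removals attributed to the first rule tripped, in that
order); samples are dropped when missingness strictly exceeds 0.10. SNP
rules run before sample rules. The HWE test is the exact conditional
test computed by the stable ratio recurrence and is checked against full
enumeration for every table with ≤ 50 genotypes. Missing calls are
filled by seeded per-SNP Binomial(2, p̂) draws. This imputer is
deliberately LD-free: it preserves allele frequencies and removes
missingness, which is all downstream stages require of it, and it is not
an accuracy-bearing component of any test.

## Numerical choices and problem sizes

* P-values are floored at the smallest positive subnormal double rather
  than returned as 0.
* Degenerate tests (monomorphic marker, single-haplotype block,
  constant PC) return P = 1 with an explicit flag instead of NaN.
* PCA/SVD signs are canonicalized; two-means initialization is at the
  extreme effects; the most frequent haplotype is always the baseline —
  every tie-break is deterministic.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; phenotype and weight-record streams are
  child streams of the genotype seed, so one config seed fixes the whole
  dataset bit-for-bit.
* Monte-Carlo checks run at sizes chosen to give comfortable margins on
  one CPU: heritability recovery at n = 1,000 × 50 replicates, scan
  calibration on 2 × 5,000-SNP null panels at n = 500, power at
  n = 1,000 × 20 replicates, boundary recovery at n = 2,000 × 30 blocks.
  At these sizes the binomial/standard-error bands quoted in the tests
  are 2–3× wider than the observed Monte-Carlo noise.

## Known limitations

* The max-effect block statistic against χ²(1) is conservative for
  blocks with many haplotypes (no max-correction), as published.
* The EMMAX approximation understates significance slightly for markers
  with very large effects; exact per-SNP REML is available for small
  panels.
* Gene windows overlap when genes are closer than twice the flank, so
  member SNP sets (and the Venn expansion built from them) are not
  disjoint across genes.
* The frequency-based imputer must not be used where imputation
  accuracy itself is the quantity of interest.
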