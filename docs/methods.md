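# Methods

This note documents the models implemented in `strainsweep`, the defaults
and why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Differentiation estimators

**F_ST.** Per biallelic site with two groups, the Weir–Cockerham (1984)
variance components are computed from genotype counts: with per-group
genotyped sample sizes `n_i`, alternate-allele frequencies `p_i`, and
observed heterozygote proportions `h_i`,

```
n̄ = (n₁+n₂)/2         n_c = n₁+n₂ − (n₁²+n₂²)/(n₁+n₂)
p̄ = Σ nᵢpᵢ / Σ nᵢ     s² = Σ nᵢ(pᵢ−p̄)² / n̄        h̄ = Σ nᵢhᵢ / Σ nᵢ
a  = (n̄/n_c)·[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
b  = (n̄/(n̄−1))·[p̄(1−p̄) − s²/2 − (2n̄−1)h̄/(4n̄)]
c  = h̄/2
```

Multi-site and per-window estimates are ratios of sums `Σa / Σ(a+b+c)` (the
"weighted" convention of the standard VCF tooling); monomorphic sites
contribute zeros and sites with fewer than two genotyped samples in either
group are not counted. Negative estimates are reported as-is. The test
suite checks this implementation against an independent, literal
ANOVA-mean-squares transcription to 1e-12 on a thousand random instances.

**D_XY.** Window D_XY is `Σ_sites [p_A(1−p_B)+(1−p_A)p_B] / L_window`, with
allele frequencies over observed alleles; unlisted positions are assumed
invariant, so they contribute only to the denominator. This makes window
D_XY × window length exactly additive across a chromosome. No
accessible-site mask is applied (the input is assumed to cover the window
uniformly); with incomplete callability D_XY is biased downward
proportionally.

**Permutation tests.** Group labels are reshuffled preserving group sizes;
the empirical p uses the add-one convention `p = (1+k)/(1+B)` so an
observed value above all `B = 100` replicates reports p = 1/101 (< 0.01),
never zero. Per-window significance permutes labels within the window and
recomputes the window's ratio-of-sums F_ST (`B_window = 199` by default);
Benjamini–Hochberg correction runs across untruncated windows with data,
and windows without informative sites are excluded from the FDR family and
logged. The per-window test is a package choice — the upstream analyses
name FDR-corrected significance without specifying the test.

**Genomic differentiation (GD).** GD is declared when the fraction of
untruncated windows with `q < α` strictly exceeds 0.90 (α = 0.05). The
fraction of windows with F_ST > 0 uses the raw, unclamped estimates.

## Sweep scan

The scan is a SweepFinder/SweeD-family composite likelihood over an evenly
spaced grid (1000 points per chromosome by default). The background model
is the chromosome-wide SFS of the scanned group, folded (minor-allele
classes) by default; an unfolded (derived-allele) mode is available and is
used for simulated data, where ancestral states are known — the unfolded
spectrum carries the high-frequency-derived excess that folding destroys,
and is substantially more powerful.

At distance `d` from a putative sweep center, each of the `n` sampled
lineages escapes the sweep independently with probability

```
p_escape(d) = 1 − exp(−(α·d)³)
```

Escaped lineages draw an allele at the pre-sweep frequency; the non-escaped
block inherits the single sweeping haplotype's allele, giving the post-sweep
class distribution `K = Bin(E, j/n) + (n−E)·Bernoulli(j/n)` with
`E ~ Bin(n, e)`. The cubic exponent is a deliberate departure from the
plain exponential: simulated footprints transition from distorted to
background spectra within a factor of ~2–3 in distance, whereas the plain
exponential spreads the shoulder over ~1.5 decades and cannot localize the
simulated sweeps at all. `α` is an inverse footprint scale (per bp); the
default grid spans footprints of ~30 kb–1 Mb plus one large value whose
footprint is below the grid spacing, which reproduces the background model
exactly and keeps the likelihood ratio nonnegative (nested null).

Each segregating site contributes its class probability conditional on
polymorphism, guarded by a 10% background admixture (`_BG_MIX`): the
idealized escape model assigns zero probability to classes it cannot
produce, and real post-sweep data (migrant-derived and recovery variants)
violates it at an appreciable rate. The composite likelihood also carries a
site-retention term — sweeps thin polymorphism near their center — whose
depth is a profiled nuisance parameter `κ ∈ {0, 0.5, 1}` scaling between no
thinning and the escape model's own retention probability. Profiling κ
decouples trough depth from spectrum shape, which matters under migration:
gene flow replenishes polymorphism near the swept site faster than the
no-migration model predicts.

**Outliers.** A grid point is an A-specific outlier when its robust z-score
`(CLR − median)/(1.4826·MAD)` exceeds 6 and the nearest grid value of the
other group's scan is at or below that scan's 0.9 quantile; adjacent points
merge into intervals. When the CLR field is mostly zero (MAD = 0, the
typical null), the fallback flags only points above both the 99th
percentile and a Bonferroni χ²(2) bound over grid points × scales (≈ 26 for
a 1000-point grid) — null maxima observed in calibration (CLR ~7–15) never
reach it. Intervals overlapping windows whose mean F_ST and D_XY both
exceed their chromosome's 95th window percentile are classified
*isolation-candidate*; F_ST alone gives *differentiation-only*.

## Structure

PCA standardizes each variant by its mean dosage 2p̂ and binomial SD
√(2p̂(1−p̂)) with mean imputation of missing genotypes, then takes the SVD.
Ancestry coefficients minimize `‖X − QF‖²` for `X = dosage/2`, `Q` rows on
the probability simplex and `F ∈ [0,1]`, by alternating blocks of ten
projected-gradient steps with Lipschitz step sizes (monotone by
construction), best of five restarts, tolerance 1e-8 relative loss change.
An F1 hybrid has expected dosage `p₁+p₂`, i.e. an exact `Q = (½, ½)`
representation; the hybrid flag requires both coefficients in [0.35, 0.65],
an operational threshold for "almost equal ancestry proportions". No
regularization is applied.

## Strain assignment

The nuclear (TPI-style) call restricts PCA to a configured diagnostic locus
(coordinates are a required input — the marker gene's position depends on
the assembly), splits samples by 2-means on PC1, maps clusters to strains
through labeled reference samples (an error if references co-cluster), and
calls samples within 0.5 pooled-within-cluster SD of the cluster midpoint
ambiguous. The mitochondrial call uses the F84 maximum-likelihood distance

```
d = −2A·ln(1 − P/(2A) − (A−B)Q/(2AC)) + 2(A−B−C)·ln(1 − Q/(2C))
```

(P, Q = transition/transversion proportions; A, B, C composition terms;
base frequencies pooled empirical by default), assigns each query the
strain of its nearest reference, and reports the margin to the nearest
other-strain reference (margin < 1e-6 substitutions/site → ambiguous;
saturation → ambiguous with a warning). Nearest-reference is the
deterministic operationalization of "the clade containing known-strain
samples"; the neighbor-joining tree over all sequences is emitted alongside
for inspection. NJ uses the standard rate-corrected criterion with
deterministic lowest-index tie-breaks; negative branch estimates are
clamped to zero after logging. Saturated pairs are capped at 1.5× the
largest finite distance for tree building only.

## Forward simulator

Two Wright–Fisher populations of N diploids split from a common ancestor
after a 10 N burn-in. Each generation: fitness-weighted parent sampling in
Pop A (viability `1, 1+hs, 1+s` with h = 0.5), migrant offspring in Pop A
take both parents from Pop B with probability m (migration is strictly
B→A), Poisson crossovers (mean r·L per meiosis), infinite-sites mutation
(mean μ·L per gamete, integer positions, collisions redrawn), and removal
of globally fixed or lost sites. The selected allele enters as a single
copy in Pop A at the split and is re-seeded (and logged) if lost; neutral
control runs (s = 0) skip the insertion entirely.

**Rescaling.** `rescale_q = q` maps `N → N/q`, `μ, r, m, s → ×q`, so
N·s, N·m, N·μ·L and N·r·L are preserved; generation counts are on the
rescaled clock. The statistical tests run at q = 31 (N′ = 100, s′ = 1.55,
one replicate ≈ 2 s); s′ > 1 is a relative viability weight, outside the
diffusion regime but preserving the qualitative windowed signature, and a
dedicated test verifies that focal-window F_ST distributions overlap
between q = 4 and q = 8 on a small base configuration.

**Post-split duration.** The default is N/4 generations (not a
multi-N quasi-equilibrium): long enough for establishment, fixation, and
differential migration homogenization of the neutral background — the
focal window shows elevated F_ST *and* D_XY relative to distal windows,
and the neutral control shows no focal elevation — while keeping the
sweep's SFS footprint fresh at sampling time (it decays on a ~N/2
timescale, and at multi-N durations no scan statistic can recover it).

**Sampling.** 40 haplotypes per population are drawn and paired into 20
diploids; only sites segregating in the pooled sample are emitted
(VCF-like ascertainment).

## What the synthetic data does and does not emulate

The Balding–Nichols fixtures give iid sites with a target F_ST, planted F1
hybrids, and known truth labels — they have no linkage, no site-frequency
ascertainment bias, and no genotyping error, so tests on them validate
estimator algebra and calibration, not robustness to LD or call errors.
The forward simulator adds linkage, drift, migration and selection but
models a single 2 Mb chromosome with uniform rates, equal sample sizes,
no missing genotypes, and diploid autosomal inheritance only (the
Z-chromosome analysis treats all samples as diploid, with no sex-specific
dosage). Mitochondrial sequences evolve on a fixed clade tree under F84
without recombination or heteroplasmy. Passing tests therefore demonstrate
correctness and power under these idealized conditions; real-data behavior
additionally depends on mapping/calling artifacts the filters only partly
remove.

## Known limitations

- Sweep-center localization under the validation model is accurate to
  ~100 kb in roughly 60–75% of replicates (measured over 60+ replicates at
  several rescalings). An independent diversity-trough localizer achieves
  the same, so this is an information limit of the model at this scale —
  the footprint spans ±~150 kb of a fully hitchhiked 2 Mb chromosome and
  ongoing migration (N·m ≈ 3) blurs the trough — not an estimator deficit.
- The folded-spectrum scan is markedly less powerful than the unfolded one;
  real-data scans without an outgroup inherit that limit.
- The NMF ancestry estimator is least-squares, not likelihood-based; with
  few informative variants pure samples can sit a few percent inside the
  simplex rather than at its vertices.
- Window phase is anchored at coordinate 0 of each chromosome; no
  accessible-site masking is applied to D_XY denominators.
- Statistical test problem sizes (replicate counts, fixture sizes, q = 31
  rescaling) are the package's default study conditions; larger runs only
  require changing `SimulationConfig`.
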