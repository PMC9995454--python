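# Methods

This note documents the models, algorithms and design choices behind
`bvsmap`, and what its simulation results do and do not show about real
data.

## The spike-and-slab regression

The core model is the multiple linear regression `y = Xβ + ε` with
`ε_i ~ iid N(0, σ²_ε)`, fitted jointly over all SNPs in a window. Each
effect has the BayesC mixture prior

    p(β_j | σ²_β, π) = π N(β_j | 0, σ²_β) + (1 − π) 1(β_j = 0),

with hyperpriors `π ~ Beta(α₁, α₂)` and scaled-inverse-χ² distributions
on both variances. Defaults:

| parameter | default | meaning / rationale |
|---|---|---|
| α₁, α₂ | 1.1, 99 | prior mean of π is 1.1/100.1 ≈ 1%; an informative prior on the non-null proportion is what gives the selection its error control — a flat Beta would weaken it, especially at modest n |
| df (both variances) | 5 | small degrees of freedom: weakly informative, data-dominated at the sample sizes of interest |
| scale_eps | set so the prior mode of σ²_ε is 0.5·Var(y) | variance-partition heuristic: a 50/50 prior split between genetic and residual variance |
| scale_beta | set so the prior-mode genomic variance is 0.5·Var(y) spread over E[π]·p SNPs of average genotype variance | same heuristic on the slab side |

Genotypes are column-centered but **not** scaled: effects stay in
per-allele units. No intercept is fitted; centering both X and y is
equivalent to integrating a flat intercept out.

### Gibbs sampler

One sweep updates, in per-iteration-permuted order (reducing update-order
artifacts), every `(β_j, δ_j)` pair from its full conditional: with
residual contribution `r_j = e + x_j β_j`, `c_j = x_jᵀx_j`,
`v_j = (c_j/σ²_ε + 1/σ²_β)⁻¹` and `m_j = v_j x_jᵀr_j / σ²_ε`, the
inclusion log-odds are
`log(π/(1−π)) + ½log(v_j/σ²_β) + m_j²/(2v_j)`; an included effect is
drawn `N(m_j, v_j)`, the residual vector is updated incrementally.
Then `π ~ Beta(α₁+k, α₂+p−k)` with `k = Σδ_j`, and both variances from
their scaled-inverse-χ² full conditionals. The inner loop is
numba-compiled; the residual is exactly consistent with `y − Xβ` at
every retained draw (tested). Draws are stored sparsely (indices +
values for β, bit-packed indicators), with exact reconstruction.

Default chain: 12,000 iterations, 2,000 burn-in, thinning 5, single
chain. These are package defaults, not claims about any reference
implementation; the scaled study below uses shorter chains (stated
there). Chain length, burn-in and genotype scaling were genuinely open
choices.

### Correctness oracle

For `p ≤ 15`, the exact posterior is computed by enumerating all 2^p
inclusion patterns, integrating β out analytically
(`y ~ N(0, σ²_β X_γX_γᵀ + σ²_ε I)` via the Woodbury/determinant-lemma
forms) and aggregating in log space. The Gibbs sampler is required to
match these exact PIPs to within 0.02 at 20,000 retained draws on random
instances with fixed hyperparameters.

A subtlety worth recording: with *informative* null data, the PIP of a
truly null SNP falls **below** the prior π (the Occam factor
`√(v_j/σ²_β)` penalizes the slab); only in the weak-data limit does the
PIP revert to the prior. Both behaviours are tested.

## Overlapping local regressions

Whole-genome fits use windows of `window_size` contiguous SNPs (default
7000) with flanks of `flank` SNPs (default 2000) on each side; only the
core (window minus flanks) is retained, and window starts step by the
core size so cores partition each chromosome exactly — stepping by 5000
with a 3000-SNP core would leave 2000-SNP gaps between consecutive
cores, so gap-free tiling takes precedence over the displacement figure.
The first and last cores extend to the chromosome ends; chromosomes
shorter than one window are fitted whole. Windows are defined in
SNP-index space, not bp. Each window sees the full phenotype and is
fitted independently (per-window seeds are derived by hashing the window
span, so results are invariant to execution order); a failing window
flags its core SNPs as missing without stopping the run.

Flanks must comfortably exceed the LD range in SNP units; with ~2-kbp
spacing and LD reaching ~300 kbp, 500-SNP flanks (~1 Mbp) suffice, which
is what the scaled study uses.

## Decision rules

Per SNP, the local FDR is `1 − PIP`. A threshold rule "select PIP > τ"
has Bayesian FDR equal to the mean local FDR of the selected set;
`select_by_bfdr` picks the smallest τ on the sorted-PIP grid whose BFDR
is within the level, i.e. the most inclusive admissible set. In high-LD
regions the posterior spreads one signal over several SNPs, none
individually significant; `elevated_segments` therefore forms candidate
segments from runs of left-over SNPs with PIP ≥ 0.05 spanning ≤ 100 kbp
(both defaults chosen to keep segments "short" — well under the ~142-kbp
median of merged marginal-test segments), scores each by the posterior
probability that **any** member is active (counted directly from the
draws of the window containing the run), and admits segments greedily in
decreasing probability order while the combined set's BFDR stays within
the level. Greedy admission and the pre-computation of probabilities
before admission were open choices; both are recorded as such.

## The synthetic-genotype generator

`simulate_genotypes` is a founder-mosaic model: K founder haplotypes
(default 20) with allele frequencies from a Beta(0.3, 0.3) (U-shaped)
spectrum truncated at MAF ≥ 0.001; SNPs at exponentially spaced
positions (default mean 2 kbp); each sample haplotype copies founders,
switching between adjacent SNPs at distance d with probability
`1 − exp(−ρd)`; dosage is the sum of two independent haplotypes.

Founder haplotypes are themselves autocorrelated along the chromosome: a
latent Gaussian AR(1) per founder (lag correlation `exp(−ρd)`)
thresholded at each SNP's frequency. This matters: with founder alleles
drawn independently per SNP, the population r² can never exceed ~1/K at
*any* distance (measured ~0.05 with K = 20), which cannot reproduce the
short-range LD real panels have. Real ancestral haplotypes carry LD;
the latent-AR(1) copula supplies it while preserving the target
frequency spectrum. A single rate ρ then controls both decay channels.

ρ defaults to 1e-6 per bp, calibrated once so the binned mean r² falls
to ≈0.1 by ~300 kbp (measured 0.11), with mean r² ≈ 0.28 at short range
— long-range LD of the kind that degrades the mapping resolution of
marginal tests.

Traits are additive: causal SNPs drawn uniformly among polymorphic
columns, raw effects iid standard normal (the effect-size distribution
was not externally constrained; Gaussian matches the slab and is an
assumption, not an assertion), the genetic score rescaled to variance
h², noise variance 1 − h², and y standardized to unit variance so h² is
the causal variance share. Returned effects are on the final y scale.

What the generator does **not** emulate: population structure and
relatedness, dominance/epistasis, binary traits, mutation/gene
conversion, recombination hotspots, and the block structure of real
human LD. Passing tests therefore demonstrate the methods' behaviour
under clean polygenic additivity with smooth distance-decaying LD — not
performance on structured cohorts.

## Scaled simulation study (the package's headline numbers)

Problem sizes were chosen as the package's desk-scale study conditions:
per replicate, n = 6000 samples and 6000 SNPs at 2-kbp mean spacing
(~12 Mbp of genome), 20 causal loci at h² = 0.5 (per-locus variance
share 2.5%, so n·h²_locus = 150 — individually well-powered, the regime
in which marginal tests over-reach), K = 20, ρ = 1e-6. SNPs with
MAF ≤ 0.001 are dropped before analysis (~35% of the U-shaped spectrum,
leaving ~3900 SNPs). The tiled fit uses 3000-SNP windows with 500-SNP
flanks and 1500 Gibbs sweeps (500 burn-in, thin 2); three replicate
seeds are averaged. The two rules compared at 125-kbp mapping
resolution (a discovery is true iff within 125 kbp of a causal variant
on the same chromosome, each causal locus creditable once) are
BFDR ≤ 0.05 on SNP-level PIPs and the marginal-test rule p < 5e-8.
`scripts/acceptance.py` recomputes these from scratch.

## Evaluation conventions

Rankings: p-value ascending (marginal test), PIP descending
(spike-slab), entry-λ descending (LASSO, 1000-point log-even grid from
λ_max down to λ_max·1e-4, one shared grid across windows), RSS-reduction
descending (forward regression). Ties break by (chrom, pos, snp id);
never-entered SNPs rank last. Power counts a causal locus at most once
however many discoveries sit near it; segment discoveries measure
distance to their span (0 inside) — an extension needed for segment
rules, flagged as such. Default resolution grid: 10, 100, 125, 250,
500 kbp and 1 Mbp.

## Polygenic scores

Three constructions: (i) marginal effects of SNPs at p < threshold;
(ii) the same selection re-fitted jointly with the spike-slab model
(posterior-mean weights — this is what removes the LD double counting of
(i)); (iii) whole-genome tiled posterior means, keeping PIP > 1/1000.
The threshold grid defaults to {1e-12, 1e-10, 1e-8, 1e-6, 1e-4}.
Scoring always centers test dosages at *training* allele means (a
deliberate-leak test guards this), missing test genotypes contribute
zero deviation, and test/train splits are disjoint by construction
(fraction-based, default 20%, fixed seed). Under perfect selection the
test correlation is bounded by √h²; the bound and the ordering
(ii) ≥ (i), (iii) ≈ best (ii) are property-tested within bootstrap
error (1000 resamples by default).

## Numerical conventions and degenerate inputs

- Inclusion log-odds are clamped at ±35 before the logistic transform.
- Zero-variance genotype columns are fatal everywhere (filter first);
  QC mean-imputes missing dosages only after the call-rate filter.
- `bfdr` on an empty selection raises rather than returning 0/NaN; so
  does the empirical FDR of an empty discovery set.
- Forward regression orthogonalizes incrementally and skips candidates
  whose residual norm falls below 1e-10 of the original (collinearity).
- LASSO active sets may briefly shrink along the path (solver drop
  events); the entry ranking uses the largest grid λ with a non-zero
  coefficient and the drop count is surfaced for checking (< 1% of grid
  points in tests).
- All randomness flows from explicit integer seeds; per-stage seeds are
  derived by CRC-hashing stage names so adding a stage never shifts
  another's draws. Same seed → bit-identical outputs (tested).

## Known limitations

- Single chain, no formal convergence diagnostics; the sampler is
  validated against exact enumeration at small p and by parameter
  recovery, not by R-hat across chains.
- Non-Gaussian slabs (scaled-t, double-exponential) are out of scope.
- The BED reader handles PLINK v1.00 SNP-major files only.
- Segment probabilities require the whole candidate run to lie inside
  one fitted window; candidates longer than a flank would be refused
  (cannot occur with the default 100-kbp span cap and default flanks).
- The empirical-FDR conclusions transfer to real cohorts only insofar
  as the mosaic model's LD mimics theirs; structured or admixed samples
  will behave differently.
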