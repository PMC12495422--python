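# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the pipeline, stage by stage.

## Genotypes and quality control

Genotypes are diploid biallelic SNP dosages in [0, 2] (ALT-allele
counts), read from VCF v4.2 with cyvcf2; multiallelic and non-SNP records
are skipped and counted, missing genotypes are masked and mean-imputed
per variant wherever a total operation is needed (GReX, PRS).

QC applies, in order: variant missingness > 0.01, individual missingness
> 0.01, MAF < 0.01, Hardy–Weinberg exact-test P < 1e−6, strand-ambiguous
(A/T, C/G) variants, duplicated variant ids.  The thresholds are the
conventional pre-PRS tutorial defaults — the guideline this battery
follows names the steps but not numbers — and every threshold is a flag.
HWE uses the conditional exact distribution of the heterozygote count
with the mid-P convention (half weight on the observed table), which
keeps the test's size close to nominal at small n.  QC is idempotent, and
on fixtures whose failing variants fail exactly one filter each, the
surviving set equals the intersection of the per-filter pass sets (order
affects only the attribution of removals).

Population structure: variants are centered by mean dosage and scaled by
√(p̂(1−p̂)); the leading eigenvalue ℓ of the individual covariance is
mapped to a Tracy–Widom TW1 statistic with the moment-based
effective-marker normalization (n′ estimated from the first two spectral
moments).  TW1 quantiles are embedded as a small table (log-linear
interpolation); only the α = 0.05 decision is consumed downstream.  The
two-population generator toggle (Balding–Nichols frequencies) exists
solely to exercise this check.

## GReX prediction

Predicted expression is the weight models' linear combination of
effect-allele dosages.  Allele handling is explicit: effect allele equal
to ALT uses the dosage, equal to REF uses 2 − dosage, strand-complement
matches are complemented first; anything else is skipped and counted
(the upstream tool's behavior for QC-removed model variants is not
documented, so skip-and-count is this package's documented choice).  A
gene with no usable entries is dropped, never NaN-filled.  No intercept
or normalization is applied: downstream scoring is rank-based, so
location and scale are immaterial — which the affine-invariance tests
make precise.

## ssGSVA

The pathway score implements the single-sample GSVA default variant:

1. per gene, a Gaussian-kernel CDF across individuals, bandwidth =
   sample SD/4; genes with zero variance fall back to the empirical
   mid-rank CDF;
2. per individual, genes are ranked by these values (largest first, ties
   broken by gene order) and weighted by |rank − p/2| (τ = 1);
3. a walk down the ranking accumulates member weights (normalized by the
   total member weight) minus uniform non-member penalties 1/(p − m);
4. score = max positive deviation − |max negative deviation| ∈ [−1, 1].

Properties: membership-identical sets (after intersection with the
expressed genes) score identically — this is the mechanism that later
forces deduplication before factor analysis — and per-gene positive
*affine* transforms leave scores exactly unchanged because the bandwidth
scales with the SD.  General monotone transforms are only approximately
neutral: they reshape the kernel-CDF values, and the cross-gene ranking
of near-tied genes can swap.  Exact monotone invariance would require
ranking on within-gene ranks alone (the ECDF variant), a different
estimator than the kernel default adopted here.

Set-size filtering counts members after intersecting with the expressed
genes and exposes both published conventions as modes — "strict"
([10, 300]) and "broad" (≥ 2) — without guessing either as canonical.
The "high-ratio quantified" summary counts pathways with strictly more
than half their genes expressed.

## PRS

Summary statistics are harmonized by variant id: A1/A2 equal to ALT/REF
keeps β, REF/ALT flips its sign, strand-complement matches are
complemented then re-checked, ambiguous and unmatched records are
dropped with counts.  The score is the average-per-allele convention
Σβ·dosage/(2M) with a raw-sum toggle; only rank order matters downstream.
LD-aware shrinkage of the effect sizes is upstream of this package: the
pipeline consumes whatever per-variant effects it is given, and the
synthetic module emits posterior-like effects directly.  PRS–phenotype
association uses ties-corrected Spearman correlation (the phenotypes are
a binary group and two ordinal stages).

## Association stage

Scores (risk and pathway, both by default) are winsorized at the 0.2 /
0.8 type-7 quantiles — the trim is the named R function's default, kept
as a flag since the source procedure does not state it.  Shapiro–Wilk
normality of pathway scores is reported only as motivation: the pipeline
always proceeds with the distribution-free HHG statistic.

HHG: T = Σ over ordered pairs (i, j) of the Pearson χ² of the 2×2 table
classifying every other point k by |x_i−x_k| ≤ |x_i−x_j| and
|y_i−y_k| ≤ |y_i−y_j|; a table with an empty margin contributes 0 (hence
a constant margin gives T = 0).  The production kernel computes T in
O(N² log N)-like time (per-focal-point distance sweep with a bitset
dominance counter, numba-compiled, tie groups processed atomically) and
equals the literal O(N⁴) definition to 1e−10; permuting the pairing
reuses the x-side structures.  Permuted statistics mathematically equal
to the observed one count as extreme; a relative 1e−9 tolerance guards
float rounding of such ties (they are systematic at small N where T is
rational-valued).

Adaptive permutation: at least 1000 and at most 10000 permutations in
batches of 250; after the minimum, the pathway stops as soon as 15
permuted statistics have reached the observed one; empirical P =
extreme/total (a (k+1)/(B+1) toggle exists for users wanting strictly
positive P).  Per-pathway generator streams are spawned from one seed, so
results are independent of pathway order.

Region-level calls: Storey q-values with π̂₀ = #{p > λ}/(m(1−λ)), λ = 0.5
(π̂₀ = 1 reduces to Benjamini–Hochberg); the empirical P whose q is
closest to the 0.05 target (ties → smaller P) is selected; each pathway's
critical value is its ⌈selected P × B⌉-th most extreme permuted
statistic (clamped to [1, B]) and significance means strictly exceeding
it.  A consistency report compares these calls with the plain
empirical-P < 0.001 rule.

Behavior under a global null, which the tests document deliberately: the
selection targets a false-discovery rate, so when nothing is real the
selected empirical P is tiny and the procedure calls ~0–1% of pathways,
not the per-comparison 5%; the empirical P distribution itself is
uniform.  Power: planted monotone dependence at Spearman ρ ≈ 0.3–0.5 and
planted quadratic (non-monotone) dependence are both recovered at > 80%
recall at n = 173, while a rank-correlation caller at matched settings
misses the quadratic variant — the reason a distance-based statistic is
used at all.

## Factor analysis of pathway scores

Pathways with bitwise-identical score vectors are collapsed to one
seeded-random representative (the excluded members are reattached to the
fitted model with their representative's factor, loading and group
multiplicity).  KMO and Bartlett's sphericity test are computed on the
same Spearman correlation matrix the CFA uses, for internal consistency
(the source is silent on Pearson vs Spearman here); with two variables
KMO is 0.5 by construction.

EFA: eigen-decomposition of the Spearman matrix, components with
eigenvalue > 1 retained, loadings = eigenvector·√eigenvalue, varimax
rotation (the referenced statistical package's default rotation; none is
named in the source), iterative deletion of variables whose maximum
absolute rotated loading is < 0.6, then of factors with fewer than two
assigned variables.  The loop terminates because the variable count
strictly decreases; fewer than two survivors raise a "no admissible
model" error (the degenerate-region case).

CFA: S ≈ Σ(θ) = ΛΦΛᵀ + Θ with the loading pattern fixed by the EFA
assignment, factor variances 1, Φ free off-diagonal, Θ diagonal.
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized by L-BFGS-B from the
EFA start (Θ = 1 − communality, Φ = I), with non-positive-definite
candidates rejected by an infinite objective (the line search backs
off); tolerance 1e−6, 500 iterations, non-convergence flagged rather than
silent.  Standard errors are √ of the diagonal of the inverse observed
information of F_ML scaled by 2/(n−1); t = estimate/SE; factor sign
indeterminacy is resolved by reflecting factors to positive loading
sums.  Modification indices for fixed cross-loadings are univariate
score statistics (n−1)·g²/h from central finite differences at the
solution; they are reported, never automatically applied — freeing
parameters is an analyst's judgment, and auto-modification would overfit
silently.

## Synthetic data: what it emulates and what it does not

The generator is deterministic per seed (each stage has its own spawned
stream).  Defaults describe the emulated study: 173 individuals, MAF
uniform on [0.05, 0.5], unlinked HWE genotypes (the pipeline consumes
dosages agnostically, so LD realism buys nothing for the statistics
tested), 50 causal variants with effects N(0, 0.5²).

Coupling, the load-bearing construction: ~30% of genes are "coupled" —
they place ~4 weight entries on causal variants with weights aligned to
the causal effect signs (0.8–1.2 × β/σ), so their predicted expression
rises with the true risk score (per-gene |Spearman| ≈ 0.2–0.4 at the
defaults); background entries are N(0, 0.25²) on non-causal variants.
Planted pathways draw 80% of members from coupled genes (≥ 50% by
construction), which yields pathway-score–risk dependence of |ρ| ≈
0.3–0.55 at n = 173 — strong planted signal, chosen once as the study
condition since the source reports no effect-size distributions.  GWAS
summary effects are the true causal effects plus N(0, (0.1·σ)²) noise;
allele flips are injected as REF/ALT swaps with sign inversion (never
ambiguous pairs, which QC would remove for a different reason).

A pure-null world (no causal variants, no planted sets) draws its
optional noise effects only on variants outside every weight model:
risk score and predicted expression are both linear in the same
genotypes, so noise effects on model variants would otherwise induce a
real, if weak, dependence — a subtlety that a 500-pathway calibration
run does detect.

Ordinal stages (Braak-like 0–6, Thal-like 0–5) and the binary group are
fixed quantile cuts of a noisy latent copy of the standardized true risk
score; the noise is calibrated by bisection against a deterministic
large-sample attenuation curve so that Spearman(risk, stage) hits the
target (default 0.5, matching the reported magnitudes ~0.48–0.56).
Gene-sharing blocks (80% overlap with a 30-gene core) create correlated
pathway scores for factor-recovery testing.  The association-stage
testbed generates pathway scores directly as strength·f(z) + noise with
f linear (strength 0.5, matching the pipeline-planted magnitudes) or
quadratic ((z²−1)/√2, strength 0.8 — quadratic signal lives in the
tails, so it needs a larger variance share to survive winsorization);
a quadratic pathway–risk link cannot arise from the linear GReX pipeline
itself, which is why this variant is generated at the association level.

What passing tests do not show about real data: no LD (so no clumping
or tag-SNP behavior), no population structure beyond the two-population
toggle, no imputation uncertainty, no correlated environmental component
in expression, and planted effects stronger than typical polygenic
reality — recovery rates here certify the machinery, not field
performance.

## Problem sizes and numerical choices

The permutation-heavy checks run at the study scale they describe
(500 pathways, n = 173, 1000–10000 permutations; the planted-recall run
caps at 5000 permutations, which leaves the threshold rule's resolution
ample); multi-seed invariance tests use n ≈ 100 and proportionally fewer
pathways.  The HHG kernel needs ~0.7 ms per permutation at n = 173, so a
500-pathway calibration costs minutes, not hours.  All tie-breaks are
deterministic (stable sorts, gene order, smaller-P selection), every
stochastic step takes an explicit seed, and two identically seeded
end-to-end runs produce byte-identical output files.
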