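# Methods

This note documents the statistical models metaboqtl implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
affect results.

## Quality control and normalization

The cleaning pipeline applies four rules in order: (i) metabolites entirely
missing or entirely zero in at least one per-plate plasma pool are removed;
(ii) samples whose value lies outside `median ± 1.5·IQR` for strictly more
than 30% of metabolites are removed; (iii) samples with any remaining
missing value are removed; (iv) metabolites whose inter-plate coefficient
of variation on pool samples — sd/mean of per-plate pool means — is ≥ 30%
are removed. Rule (iv)'s direction deserves a note: a filter that removes
*low*-CV metabolites would discard precisely the well-measured ones, so the
package removes high-CV metabolites; both the threshold and the direction
are configurable and the applied rule is logged in the `QCReport`.
Boundary conventions are fixed: outlier fraction strictly > 0.30 removes;
CV ≥ threshold removes; with IQR = 0 a value deviates only if it differs
from the median. Remaining zeros (below-LOD censoring) are imputed from
`Uniform(0, min nonzero of that metabolite)` with a caller-supplied seed.

Each trait y (metabolite or pairwise concentration ratio a/b, ratios formed
on the raw imputed scale in input column order) is normalized by a Box-Cox
transform, `y(λ) = (y^λ − 1)/λ` (λ ≠ 0) or `log y` (λ = 0), with λ chosen
by maximizing the profile log-likelihood

    ℓ(λ) = −(n/2)·log(RSS(λ)/n) + (λ − 1)·Σ log y

of a regression on intercept, carcass weight (kg), sex, and J−1
collection-date dummies (breed added for combined-cohort analyses). The
search is a fixed grid of 3001 values on [−3, 3] (spacing 0.002; λ = 0 is
a grid point). The 95% interval collects grid values within
χ²₁(0.95)/2 = 1.92 log-likelihood units of the maximum. For network
construction a single λ — the grid value covered by the most per-trait 95%
intervals, ties broken toward the median of the per-trait MLEs — replaces
the per-trait λ. Residuals e = y(λ) − ŷ from the covariate fit are the
traits used downstream; because the design always carries an intercept,
residuals sum to zero and residualization is idempotent.

λ is weakly identified when a trait's relative spread is small (the
transform family is locally affine over a narrow range); the 95% intervals
are honest about this, which is exactly why the common-λ selection works
on intervals rather than point estimates.

## Kinship and heritability

The pedigree additive relationship A uses the tabular method
(A_ii = 1 + F_i, A_ij averages the relationships of j's parents with i),
with ancestors deeper than four generations treated as founders. The
genomic relationship matrix is the centered form K = Wc·Wcᵀ/p (Wc the
per-SNP mean-centered dosage matrix, p the SNP count; a standardized
variant is available). Missing dosages are mean-imputed per SNP inside GRM
and LD computations only; stored data keep their missing values.

Variance components of y = μ + g + e, g ~ N(0, σ²_g K), e ~ N(0, σ²_e I)
are estimated by REML after a single eigendecomposition of K, profiling
σ²_g out and optimizing the ratio δ = σ²_e/σ²_g by a coarse grid plus
Brent search on log δ ∈ [−10, 10]. Because the centered GRM's mean
diagonal is the average per-SNP dosage variance (not 1), heritability is
reported as

    h² = k̄·σ²_g / (k̄·σ²_g + σ²_e),   k̄ = mean(diag K),

which makes the estimate invariant to the overall scaling of K and
comparable between pedigree (k̄ ≈ 1) and genomic kinships. Estimates pinned
at the search boundary are flagged and truncated into [0, 1]; a flat
likelihood (e.g. K ∝ I, where only σ²_g + σ²_e is identified) is flagged
rather than reported as a number. The standard error of h² comes from the
numerical curvature of the profile REML log-likelihood in h². Covariates
are removed before heritability estimation (the model is intercept-only on
residuals).

## Association scans

Per SNP x the model is y = Wα + xβ + g + e (W = intercept), tested with a
Wald statistic from generalized least squares under
V = σ²_g K + σ²_e I, computed in the eigenbasis of K so each SNP costs
O(n). Two modes: `exact` re-optimizes δ per SNP by REML (the default);
`null_vc` fixes δ at the null-model fit and is used for large scan
volumes. The two agree closely for ordinary SNPs; per-SNP re-optimization
can shift P by more than 1.5× for the few SNPs that load strongly on the
genetic structure itself, and the gap grows in the extreme tail — an
inherent property of the fixed-δ approximation, not a defect of either
path. The Wald test uses the normal approximation throughout (no
small-sample t correction); the residual variance in the test is estimated
at n − 2 degrees of freedom. Monomorphic SNPs yield missing statistics
with a flag.

Per-SNP variance explained is
PVE = 2β̂²·maf(1−maf) / (2β̂²·maf(1−maf) + se²·2n·maf(1−maf)); the maf
factor cancels algebraically, which the tests assert.

Multiple testing uses an LD-based Bonferroni threshold α/m_eff, where
m_eff counts survivors of greedy windowed LD pruning (window 100 SNPs,
step 5): for every pair with r² ≥ 0.25 (composite LD on mean-imputed
centered dosages) the lower-MAF SNP is dropped, ties broken toward the
larger position. A plain Bonferroni over the SNPs shared between cohorts
is also emitted for meta-analysis.

Ratios are tested like any trait; the p-gain
min(p_a, p_b)/p_ratio quantifies what the ratio adds over its components.
The critical level is 10 × the number of tested ratios (an FWER-style
bound per SNP across the ratio panel); a ratio is called significant when
its p-gain exceeds that level *and* the ratio itself passes the
single-trait threshold (the conjunction is configurable).

Meta-analysis uses the sample-size-weighted Z-score:
Z_i = sign(β_i)·Φ⁻¹(1 − p_i/2), w_i = √N_i, Z_meta = Σw_iZ_i/√(Σw_i²).

mQTL regions merge significant SNPs of one analysis context on a
chromosome while consecutive positions are < 1 Mb apart; clusters from
different contexts merge when their spans come within 0.5 Mb. The lead is
the most significant member (ratio-only members ranked by p-gain). Genes
overlapping the closed interval ±500 kb around the lead SNP are attached,
sorted by distance.

## Gaussian graphical models

Full-order partial correlations come from inverting the Pearson
correlation matrix: PCC_ij = −Ω_ij/√(Ω_ii·Ω_jj). Edges require PCC > 0.3,
strict and signed (an absolute-value mode exists as a switch; networks of
biological concentrations are dominated by positive partial correlations,
and the threshold convention follows that reading). If the correlation
matrix's condition number exceeds 1e10 a ridge of 1e−4 is added to the
diagonal and the result flagged — with n ≫ m this never triggers. The
genotype-corrected variant first replaces each metabolite by its residuals
on an intercept plus dummy-coded (het / hom-alt indicator) lead-SNP
genotypes, then recomputes both correlation matrices; monomorphic leads
are dropped with a warning. The matrix-inversion estimator is checked in
the tests against a brute-force oracle that correlates the residuals of
each pair regressed on all remaining metabolites.

## Kynurenine-pathway kinetics

All pathway reactions are enzymatic and assumed far below saturation
([S] ≪ K_M), so each rate is first order, v = (k_cat/K_M)·[E]·[S] = k·[S],
and the system is linear. Topology: Trp → KYN (TDO/IDO); KYN → KA (KAT),
KYN → AA (KYNU), KYN → HK (KMO); HK → XA (KAT), HK → HAA (KYNU);
HAA → QUIN (3HAO). Design choices:

- **Trp is a clamped boundary driver**, not a dynamic species: steady
  states are expressed as functions of the Trp level, and the basal vs
  supplemented feeding conditions are simply two Trp values.
- **Terminal species (KA, AA, XA, QUIN) carry a first-order clearance**
  k_clear (shared constant by default, per-species configurable) so their
  steady states exist.
- Steady states are derived from mass balance on this topology — e.g.
  HKss = k_KMO·KYNss/(k_KAT2 + k_KYNU2) — and verified against stiff
  numerical integration (LSODA) in every test; the closed form and the
  integrator agree to better than 1e−6 relative across random parameter
  sets.

Units follow the human-derived k_cat/K_M constants (s⁻¹ mM⁻¹ with enzyme
level folded in): k_KMO = 22, k_KYNU1 = 0.46, k_KAT1 = 2.08; unspecified
constants default to 1. Only ratios of constants matter for steady-state
concentration ratios, which is what every analysis here uses. Because
HKss ∝ k_KMO/(k_KAT1 + k_KYNU1 + k_KMO), the HK level is insensitive to
k_KMO whenever k_KMO ≫ k_KAT1 + k_KYNU1 (log-sensitivity
(k_KAT1+k_KYNU1)/(k_KAT1+k_KYNU1+k_KMO) ≈ 0.10 at the human constants):
doubling k_KMO moves HKss by ≈ 5.5% while KYNss drops by ≈ 47% — a
KMO-activity variant shifts kynurenine, not 3-hydroxykynurenine. Group
comparisons use the two-sided Wilcoxon rank-sum test, exact for group
sizes ≤ 12 without ties, otherwise the tie-corrected normal approximation.

## Synthetic-data generator

The generator emulates the statistical structure of a two-breed pig
cohort: a litter-structured pedigree (random mating of the previous
generation, litters of three full sibs; breed presets approximate ~790 and
~290 animals over ≤ 4 generations), SNP-chip genotypes by gene dropping
(founder haplotypes from a first-order Markov / AR(1)-Gaussian-copula
model with adjacent-SNP latent correlation ρ, default 0.8; per-SNP MAF
uniform on (0.05, 0.5]; meiosis with ~1 expected crossover per
chromosome), and a metabolome generated as

    u = μ0 + s·(covariates + Σ x·β_snp + g + ε),
    g ~ N(0, h²·K̃),  ε rows ~ N(0, corr(Ω⁻¹)) scaled by √(1−h²),

observed through the inverse Box-Cox transform at per-metabolite λ
(λ ∈ {0, 0.25, 0.5, 1} by default, so positivity is guaranteed after the
affine map with μ0 = 3, s = 0.5), then censored and contaminated. Fixed
covariates (carcass weight ~ N(90, 8) kg, sex, collection date with 5
levels) jointly explain ~20% of the latent variance by default. Planted
mQTL are specified by target PVE; the allele effect is
β = √(PVE/(1−PVE)/(2·maf·(1−maf))) on the unit-variance latent scale
(negative target PVE plants a negative effect — useful for constructing
true ratio-QTL as opposite effects on a correlated pair). Zero-masking
replaces the smallest `zero_rate` fraction of each metabolite with 0
(mimicking below-LOD censoring, not random dropout); sample outliers
multiply > 30% of a sample's metabolites by a shared factor so the
IQR-based sample rule has true positives. Plates are assigned round-robin.
A single global seed fans out deterministically to per-stage generators.

What the generator does **not** emulate: realistic recombination maps or
allele-frequency spectra, selection, breed-specific LD structure,
measurement heteroscedasticity beyond the lognormal/outlier model, and
instrument batch drift beyond the fixed plate/date effects. Passing
recovery tests on this generator therefore demonstrates the estimators'
correctness under the assumed generative model, not performance on any
particular real cohort.

The default zero rate (0.02) is a configurable placeholder: instrument
censoring rates vary by panel and matrix and no canonical value exists.

## Problem sizes used in the shipped checks

The shipped end-to-end checks run at desk scale, chosen so each exercises
the full pipeline while completing in seconds to a couple of minutes: the
type-I calibration uses ~300 animals × 2000 SNPs × 20 traits (40,000 null
tests); heritability recovery ~500 animals × 5000 SNPs × 20 replicate
traits per h² level; ratio-QTL recovery 20 replicates of ~240 animals ×
200 SNPs × 8 metabolites (28 ratios scanned, evaluated against the
study-scale p-gain critical level of 10 × 14,196); GGM recovery 20
replicates of a 20-node chain at n = 800. The LMM and PCC estimators are
additionally pinned to dense brute-force oracles at small n, where exact
agreement (1e−8) is the criterion rather than statistical recovery.

## Known limitations

- The exact-mode scan re-optimizes variance components per SNP but keeps
  the tested SNP inside K (no leave-one-chromosome-out), so strong QTL
  suffer mild proximal contamination, as in the standard single-K LMM.
- The Wald normal approximation is slightly anticonservative at small n;
  calibration was verified at n ≈ 300, not below.
- REML standard errors come from numerical profile curvature and are
  approximate near the h² boundaries.
- The Box-Cox grid bounds λ to [−3, 3]; traits needing more extreme
  transforms hit the boundary and are flagged only via the CI.
- Ratio normalization transforms the raw ratio (not the log-ratio
  difference); after a log transform the two coincide, and the p-gain is
  invariant to numerator/denominator swap exactly in that case,
  approximately otherwise.
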