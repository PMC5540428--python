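# Methods

This note records the models implemented in twinscales, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Latent-trait assignment and kernel IRT

Respondents complete in all scale items are ranked by the scale sum score;
ties are broken by a uniform jitter generated deterministically from
(person id, tie seed), so the assignment is invariant to row order. Person
i with rank r_i among N receives θ_i = Φ⁻¹((r_i − 0.5)/N). This is the
classic rank-transform construction of kernel-smoothed IRT: it assumes the
sum score stochastically orders respondents on the latent trait (SOL),
which holds in practice for scales with more than five items and few
response categories — the reason `refine_scale` refuses to shrink a scale
below six items.

Option curves are Nadaraya–Watson estimates
p̂_jk(θ_q) = Σ_i K((θ_q−θ_i)/h)·1[x_ij=k] / Σ_i K((θ_q−θ_i)/h)
with a Gaussian kernel; step functions are cumulative sums, so
Σ_k p̂_jk = 1 and S₁ ≥ S₂ hold by construction. Confidence bands use the
kernel-weighted binomial approximation with effective sample size
n_eff = (Σw)²/Σw², clipped to [0, 1]; a bootstrap is deliberately not the
default — the bands feed a CI-overlap rule, where a fast deterministic
approximation is adequate.

Defaults: grid of 51 equally spaced points on [−3, 3] (the extent makes an
all-lowest respondent score exactly −3, the boundary value reported for
zero-sum respondents); bandwidth h = 1.1·N^(−1/5), the standard kernel-IRT
rate. ML scoring maximizes Σ_j log max(p̂, 10⁻⁶) over the grid; the floor
prevents −∞ from smoothing zeros and ties resolve to the lowest grid
point.

Item difficulty/discrimination coordinates come from a centred PCA of the
items × grid matrix of expected scores. The leading component usually
carries difficulty, but for item sets varying mostly in slope it carries
discrimination instead, so the two semantic axes are *assigned* to
whichever principal components they load on (by correlation with the mean
expected score and with the curve's total variation respectively), then
oriented so that higher = easier and higher = more discriminant.

## Screening rules

*Monotonicity*: an item is flagged when a step function falls more than
0.05 below its running maximum over at least two consecutive grid points
inside the central 95% of the latent density ([−1.96, 1.96]). Decreases
confined to the tails are recorded as evidence but not flagged — an
extreme-tail wobble affects almost nobody's ordering.

*Endorsement*: an item is flagged low-endorsement when the upper 95% band
of S₁ never reaches 0.95 at any grid point with n_eff ≥ 30. The naive
version of this rule ("band below 0.95 at the top grid point") is
worthless in practice: at the extreme grid points a handful of respondents
carry all the kernel mass and the binomial band always touches 1. The
n_eff floor restricts the judgement to where the fit is informative. A
category with zero observed responses raises a separate empty-category
flag. A side effect worth knowing: an extremely difficult but otherwise
clean item can be flagged, which matches the protocol's intent of dropping
items informative only about a small subgroup.

*Refinement* excludes all flagged items per iteration and refits before
re-judging, because flags can be artefacts of poorly fitting co-items
distorting the pooled ranking. Candidates are admitted singly when
unflagged and when their discrimination coordinate exceeds the scale's
lower quartile — a formalization of "adds information"; the quartile is
configurable.

*DIF*: groups are compared on a common metric (pooled ranking, per-group
curves, shared bandwidth). The statistic is the standard-normal-density
weighted RMS difference of step functions (a mean-absolute variant is
available); an item's DIF is the maximum over its two step functions
(conservative). Exclusion needs DIF > 0.25 *and* band disjointness over a
contiguous region carrying ≥ 10% of latent mass — the published rule says
"significant as indicated by the 95% confidence intervals" without an
explicit region criterion; the 10% mass threshold is this package's
operationalization and is exposed in the module constants. Whether the DIF
integral should be density-weighted or uniform is likewise unstated in the
literature this follows; density weighting was chosen because differences
where nobody sits should not drive exclusions.

## Psychometrics

α uses the variance-ratio definition on complete cases. Loevinger
coefficients use the comonotone (sorted-marginals) upper bound for the
covariance of two polytomous items; H_i and H aggregate covariances before
dividing, the standard weighting. Mokken classes need all H_ij > 0 and
then read min H_i against 0.3/0.4/0.5. Constant items are excluded with a
warning. ICC is the two-way consistency coefficient ICC(C,1) from the
ANOVA mean squares with the F-based confidence interval; consistency (not
absolute agreement) is the right flavour for test-retest, since a uniform
shift between occasions is not unreliability. Winsorisation clips at
mean ± 3 SD of the *input* moments; it is not idempotent by construction
and is not claimed to be. The sex-difference test is a linear mixed model
with covariance σ_g²K + σ_e²I fitted by ML after family-wise
eigen-rotation, with an OLS-consistent Wald t (the residual variance is
rescaled by n/(n−p), so the identity-kinship case reproduces the ordinary
t-test exactly).

## Pedigree operations

The relatedness matrix uses expected additive coefficients: 1 for MZ
co-twins, 0.5 for DZ co-twins, twin–sibling and sibling–sibling pairs,
0 across families. Familial pruning draws one member per family 1000
times and keeps the draw minimizing
|Δmean age|/SD + |var ratio − 1| + |Δfemale fraction| — the three matching
criteria named by the study protocol combined as an unweighted sum, since
no composite metric is published. Age bins are half-open
[9,13), [13,15), [15,17), [17,28] (the Methods wording wins over a
conflicting table header on the lower bound). Family size is restricted to
the twin pair plus one seeded-random extra sibling.

## Twin models

FIML: each family contributes the MVN density of its observed members;
families are grouped by covariance pattern so likelihood evaluations are
batched. Fixed effects are profiled out by GLS at every evaluation.
Optimization is over unbounded path coefficients (variances = squares,
non-negative by convention) with seeded Nelder–Mead multi-starts.
Standardized proportions are computed post-fit; their 95% CIs are
profile-likelihood intervals found by bisection on the constrained
likelihood (the published brackets are asymmetric, which delta-method CIs
cannot reproduce). Nested-model LRTs use the naive χ² reference, matching
common twin-literature practice; the boundary (50:50 mixture) correction
is a documented caveat rather than the default. C and D are never fitted
simultaneously (unidentified in twin-only designs).

The omnibus homogeneity test compares a saturated model (per-zygosity
bivariate normal with free means, variances and covariance — closed-form
MLE) against an equal-means-equal-variances model with free per-zygosity
correlations, on complete twin pairs. With two zygosity groups this is a
6-df test; the df is always reported from the actual parameter-count
difference rather than fixed at a published value, because the saturated
parameterization that yields exactly 20 df also includes sibling and
birth-order strata not identifiable in every simulated design. The
sex-limitation check fits sex-specific A/E paths over the five
zygosity-by-sex groups (opposite-sex covariance 0.5·a_F·a_M) against
shared paths (2-df LRT), means per sex in both models.

The bivariate model is a Cholesky parameterization per component
(Σ = LL' with 2×2 lower-triangular L for A and E, plus C for ACE);
rG = Σ_A[1,2]/√(Σ_A[1,1]Σ_A[2,2]) and analogously rE. Constrained refits
(l_A22 = 0 for rG = 1, l_A21 = 0 for rG = 0, l_E22 = 0 for rE = 1) give
the boundary LRTs. The model-implied phenotypic correlation decomposes
exactly into the component parts at the optimum.

## Association

PQL: iterate (i) working response z = η + (y−μ)/W, W = μ(1−μ); (ii) ML
update of σ² in the working Gaussian model (1-d bounded search, block
algebra); (iii) GLS for β and BLUP for u with V = W⁻¹ + σ²K. K is block
diagonal by family, so everything is batched over same-size families.
Wald t with df = n − rank(X). PQL is known to attenuate |β| slightly for
binary responses; at the variance magnitudes used here the attenuation is
within the recovery tolerances, and the choice mirrors the
quasi-likelihood approach the pipeline is modelled on. Separation is
flagged at |β̂| > 15 and non-convergence after 100 cycles is reported,
not raised.

The effective number of tests uses the Li–Ji estimator
np = Σ(1[λ≥1] + frac(λ)) on the (pairwise-complete) score correlation
matrix; eigenvalues are rounded to 10 decimals first, because an
eigenvalue of 3 − 10⁻¹⁵ must not contribute a fractional part of ~1, and
the result is clipped to [1, M]. A Nyholt variant sits behind a flag; the
two published citations leave the exact estimator ambiguous, and Li–Ji is
the stricter, more common choice. The corrected threshold is
α/(np · #outcomes).

## Synthetic cohorts

The generator draws A/C/E component scores per person so that MZ co-twins
share A exactly, any other pair of children correlates 0.5 on A, and C is
family-constant; cross-trait correlations rG/rC/rE are imposed on every
independent draw, so the implied component correlations are exact in
expectation. Latent traits are standardized before covariate shifts.
Items follow a graded-response construction S_k = d·σ(a(θ−b_k)) with
optional group threshold shifts (DIF), upper asymptotes d < 1
(low endorsement) and a Gaussian bump subtracted from S₁ (non-monotone),
clipped to keep S₁ ≥ S₂. Retest administrations use
θ' = ρθ + √(1−ρ²)·noise with ρ defaulting to 0.47, the published
anxiety-depression retest consistency. Diagnoses follow
logit p = β₀ + βθ + u with u ~ N(0, σ²K) drawn family-wise; defaults are
β₀ = logit(0.16) (the published MDD prevalence), β = log(1.39) (the
15-16-year anxiety-depression→MDD odds ratio) and σ² = 0.3, a modest
familial aggregation beyond the score effect chosen once as a realistic
magnitude.

Default composition matches the youngest genetic-analysis age bin: 226 MZ
pairs, 408 DZ pairs, extra-sibling probability 84/634, 28 singletons, ages
N(12, 0.4). Default item banks are calibrated so the zero-score
proportion of a 14-item scale lands near a fifth of respondents, the
range observed in the community samples this emulates; with those
defaults the simulated scales reproduce α ≈ 0.86, scale H ≈ 0.40 and all
pairwise H_ij > 0 without any tuning toward those statistics.

What the generator does **not** emulate: item-level missingness mechanisms
beyond optional MCAR masking, age trends within bins, assortative mating,
twin-specific shared environment, sex-specific variance components, and
selection/attrition. Passing tests therefore demonstrate correctness of
the estimators under the stated generating model, not robustness to those
real-data complications.

A note on detectability that shaped the screening item bank: rank-based
latent scoring plus kernel smoothing acts like convolving the true curve
with noise of roughly 0.4–0.6 SD, so narrow response-curve dips (width
≲ 0.5) are invisible in the fitted curves no matter how deep. The
packaged pathological items use broad post-peak declines (width ≥ 1.1,
depth ≥ 0.55) — the kind of violation visual inspection protocols are
actually built to catch. Replicated screening on 20 cohorts of 1200
respondents excludes all six pathological items and retains all nine
clean anchors in ≥ 19/20 runs.

## Problem sizes

The recovery experiments use 20 replicates at the study's family
composition (heritability), 20 replicates of 600 twin+sibling families
(bivariate correlations), 200 replicates of 52 retest pairs (ICC) and 20
replicate cohorts of ~1900 individuals (odds ratio); calibration-style
tests use 25–200 replicates at a few hundred families each. These sizes
give Monte-Carlo standard errors several times smaller than the
tolerances they are checked against.

## Known limitations

- The rank-transform θ is only defined up to the SOL assumption; scales
  with many strongly heterogeneous discriminations weaken it.
- PQL attenuates odds ratios for high random-effect variances; for
  σ² ≳ 1 a quadrature-based fit would be preferable.
- The homogeneity and sex-limitation tests use complete twin pairs only;
  siblings and singletons inform the variance-component fits but not the
  assumption checks.
- Profile CIs assume a unimodal profile; multi-start optimization makes
  this reliable but not guaranteed.
- `cross_wave_select` optimizes wave balance greedily within seeded
  draws; it is an argmin over its own candidate set, not a global
  optimum.
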