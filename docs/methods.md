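# Methods

`twinpath` implements the classical twin design: variance in a phenotype
measured on monozygotic (MZ) and dizygotic (DZ) twin pairs is decomposed
into additive genetic (A), shared-environment (C) and unique-environment
(E, including measurement error) components, identified by the contrast
between MZ pairs (additive-genetic latents correlated 1.0) and DZ pairs
(correlated 0.5 under random mating; the DZ correlation is a module
constant so assortative-mating values can be substituted). Shared
-environment latents correlate 1.0 in both groups — the equal-environments
assumption — and E latents are independent. All latents are standard
normal; scale lives in the path coefficients, so squared paths are variance
components.

## Models

**Univariate ACE family.** One phenotype per twin; expected moments per
zygosity group are Var = a² + c² + e², cross-twin Cov = r_A a² + c² with
r_A ∈ {1, ½}; means equated across twin order and zygosity (one `b0`).
Sub-models AE / CE / E fix the dropped path at zero. The saturated
comparison model estimates per-group means, variances and the cross-twin
covariance freely (EP = 10).

**G×E moderation (Purcell-style).** Each path becomes a linear function of
a pair-level moderator M (childhood SES in the emulated study): a(M) =
a₀ + a₁M, etc., and the mean becomes b₀ + b_M·M. The moderator is
pair-shared by default, since a rearing-family variable is a property of
the pair; an individual-level mode exists behind a flag. The moderation
test drops the three slopes (a₁, c₁, e₁) jointly — a 3-df likelihood-ratio
test; the mean-moderation term b_M stays in the reduced model so the mean
structure does not confound the variance test.

**Common-pathway model (CPM).** f latent psychometric factors, each with
its own unit-variance ACE decomposition (a_F² + c_F² + e_F² = 1), load on
all p items through a free p×f loading matrix; each item additionally
carries specific A/C/E paths. Within-twin covariance is ΛΛᵀ + diag(specific
totals); cross-twin covariance is Λ diag(r_A a_F² + c_F²) Λᵀ + diag(r_A
a_s² + c_s²). The "no C" / "no A" reductions drop the component's factor
path(s) *and* all its item-specific paths (f + p parameters here).

**Independent-pathway model (IPM).** Separate A-, C- and E-common loading
matrices (p×f each) act directly on the items, plus item specifics; no
variance constraints. Every CPM is an IPM via loadings-times-path (the
nesting identity used both as a warm start and as an exact moment-equality
test).

**Direct variance–covariance baseline.** Full symmetric A, C, E component
matrices are estimated directly (within = A + C + E, cross = r_A·A + C)
with *no* positive-semidefiniteness constraint on the individual
components; only the total within-twin covariance must be positive
definite at evaluation. This is the saturated twin-design baseline that
avoids the boundary bias a Cholesky-parameterized baseline would impose on
components whose ML solution is indefinite.

## Estimation

**FIML.** Every pair contributes the Gaussian deviance of its observed
entries only: k·ln 2π + ln|Σ_obs| + quadratic form, with Σ_obs, μ_obs the
rows/columns of its group's expected moments selected by the pair's
missingness pattern. A wholly missing co-twin reduces to the single twin's
marginal density; nothing is imputed. For models whose moments are constant
within a group the sum is accumulated per missingness pattern from
sufficient statistics (n, Σx, Σxxᵀ), making one deviance evaluation
independent of sample size; the moderated model, whose moments vary by
pair, is evaluated with vectorized per-pair 2×2 closed forms. Non-positive
-definite sub-matrices yield +∞ (a large finite penalty inside the line
search).

**Optimization.** Multi-start L-BFGS-B with numerical gradients; the first
start is a moment-based heuristic (sample moments shrunk 10% toward the
diagonal and decomposed by the MZ/DZ method-of-moments identities), later
starts jitter it ±20% (multi-factor models additionally apply random
orthogonal rotations to the loading block). Warm starts mapped through the
nesting identities (CPM f → f+1, CPM → IPM, full CPM → reduced CPM) are
supplied by the pipeline; this both speeds convergence and guarantees the
fitted deviances respect the nesting ladder. Convergence: relative deviance
tolerance 1e-12, evaluation budget 5000 + 800·dim per start (finite
-difference gradients consume dim+1 evaluations per step). The restart loop
stops early once three starts agree with the best deviance to 1e-6; a fit
that never converges is reported `failed`, never silently accepted.

**Constraints and signs.** The unit factor variance of the CPM is enforced
exactly by spherical angles (a_F = cos θ₁, c_F = sin θ₁ cos θ₂, e_F =
sin θ₁ sin θ₂); the ledger still counts three free factor paths plus one
nonlinear constraint per factor, so comparison df follow the usual
convention: df = ΔEP + Δconstraints, the more-constrained model
contributing its constraints positively (a 1-factor CPM against the p=6
baseline: 69 − 33 free parameters + 1 constraint = 37 df). The likelihood
is even in every path, so the fitted solution is canonicalized to the
non-negative representative (loading columns flipped to positive sum);
confidence intervals are computed on the signed parameterization and may
cross zero.

**Uncertainty.** Profile-likelihood 95% intervals: bounds where the profile
deviance exceeds the minimum by χ²₁(0.95) = 3.8415, found by bracket
expansion and bisection to 1e-4, re-optimizing nuisance parameters warm
-started from the previous profile point (coordinate-fixing where the
parameter is an internal coordinate, SLSQP with an equality constraint
otherwise). Wald SEs come from the numerical deviance Hessian with a delta
-method Jacobian onto the reported parameters; they seed the profile
bracket and provide the SEs printed for multivariate loading tables.

## Model comparison

Likelihood-ratio tests require structural nesting, validated on the model
objects; Δ−2LL that is negative beyond numerical noise (−1e-6) is an error,
tiny negative noise is clamped to zero with a warning. The best-CPM vs
best-IPM row follows the quasi-nested likelihood-comparison convention when
the IPM is the larger model (the study design this emulates compares a
3-factor CPM with a 2-factor IPM on 12 df). Boundary effects on the null
distribution of variance-component tests are ignored — plain χ² reference
throughout — a deliberate, documented approximation; the calibration suite
therefore exercises the moderation LRT, whose null (zero slopes) is an
interior point. AIC = −2LL + 2·EP; Akaike weights are
exp(−ΔAIC/2)/Σexp(−ΔAIC/2), shift-invariant and reported to 2 dp.
P-values below 0.001 render as "< 0.001".

## Phenotypic statistics

Cronbach's α, Horn parallel analysis and a single-factor ML factor analysis
(statsmodels' ML factor routine on the sample correlation matrix, loadings
sign-fixed to positive sum, Heywood solutions flagged and capped) describe
the items before biometric modelling, using listwise deletion and one
randomly selected twin per pair (seeded) to respect the non-independence of
co-twins. Parallel analysis reports adjusted eigenvalues on the mean
convention (observed − mean random + 1, the scale on which such analyses
are usually quoted) but *retains* factors by the sequential 95th-percentile
rule: retain leading ranks while the observed eigenvalue exceeds the 95th
percentile of the rank's random eigenvalues. The mean rule is available via
`retention="mean"`, but on pure noise it retains a spurious factor roughly
half the time (the top observed eigenvalue fluctuates symmetrically around
the random mean), whereas the percentile rule holds the false-retention
rate at the nominal 5% (measured 5–7% at p = 6, n = 750).

## Synthetic data

The generator draws the exact latent structure the models assume, so the
implied moments equal the corresponding moment builders by construction
(verified to 4 Monte-Carlo SEs at 20,000 pairs/group). The default study
conditions emulate a mid-life US twin sample: 278 MZ and 478 DZ pairs, six
items on a 1–4 scale. The default item truth is a 3-factor common-pathway
configuration — a general factor with mixed A/C/E influence loading on all
items, an A-dominant factor on an advice/teaching subset, and a pure-E
factor — with E-heavy specifics, chosen so the implied item-level twin
correlations fall in the 0.1–0.3 band for MZ pairs with DZ values above
half the MZ ones (realized group averages ≈ 0.21 MZ / 0.15 DZ). The default
scale-score truth uses standardized shares 0.09 / 0.16 / 0.75. Likert
scores are produced liability-style: the linear ACE composition is computed
first and cut at thresholds (−0.9, 0.3, 1.3), calibrated to item means near
2.2 and SDs near 0.85 rather than symmetric quartiles; the analysis treats
the resulting 4-point scores as continuous, as the emulated study does.
Whole-co-twin missingness is generated at a configurable rate (default 2%
in the study config); pairs losing both twins are dropped.

What the generator does **not** emulate: ordinal measurement error beyond
the threshold cut, item-specific threshold variation, age/cohort structure,
selective attrition, or assortative mating. Passing tests therefore show
that the estimators recover the generating process under the stated
assumptions — not that those assumptions hold in real survey data.

## Recovery and calibration conditions

Two properties of twin models shape the test design and are worth stating
plainly:

- **Paths at zero are not root-n estimable.** The likelihood is even in
  each path, so at a true value of zero the score vanishes identically and
  the path is estimable only at the n^(−1/4) rate; fixed-tolerance path
  recovery is meaningless there (observed errors 0.1–0.4 at 20,000
  pairs/group for the default truth's zero paths, with the global optimum
  verified). Variance *components* (squared paths) remain root-n regular.
- **Factor rotation is identified only through cross-twin weight
  contrasts.** Two factors with similar (r_A a_F² + c_F²) profiles leave
  the likelihood nearly flat along their rotation; the default study truth
  has exactly this property (DZ weights 0.325 vs 0.35), mirroring the
  power limits of the study design it emulates.

Parameter-recovery tests therefore use a dedicated well-identified
configuration (`recovery_item_params`): near-simple-structure loadings,
every path bounded away from zero, separated weight profiles — chosen by
power analysis so that the recovery tolerances sit at ≥ 2–3 asymptotic SEs
(every factor-path SE ≤ 0.017, loading SE ≤ 0.025 at 20,000 pairs/group).
Null calibration of the moderation LRT runs 500 replicates at 600 MZ /
1000 DZ pairs: at a few hundred pairs the 3-df test is visibly conservative
(a finite-sample property, verified not to be an optimization artifact),
while at this size the χ²₃ reference is accurate (KS p ≈ 0.87, type-I
≈ 0.047 in pilot runs).

## Problem sizes

Defaults used by the test suite and the acceptance script, chosen to make
Monte-Carlo error small relative to each tolerance: recovery fits at
20,000 pairs per zygosity group (sufficient-statistic FIML makes fit cost
independent of n); the synthetic study ladder at the emulated 278/478;
moment-fidelity checks at 10,000–20,000 pairs/group; LRT calibration at
500 replicates of 1,600 pairs; profile-CI coverage spot-checks at 60
replicates of 600 pairs.

## Known limitations

No dominance (D) component, sex-limitation or assortative-mating models;
no ordinal liability-threshold fitting (Likert items are analysed as
continuous, matching the emulated study); no analytic gradients; no
sandwich/robust standard errors; LRT boundary mixtures are not applied.
The direct variance–covariance baseline requires enough pairs for 69 free
parameters — at very small n its ML solution is noisy and the nesting
ladder comparisons lose meaning.
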