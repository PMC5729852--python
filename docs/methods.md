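# Methods

## Model

### Biometric layer

For twin pair *i* with family-level moderator *M_i*, the latent traits
(θ_i1, θ_i2) are bivariate normal with

* mean: μ + β₁ₘ M_i (both twins),
* common variance: σ²_A(M_i) + σ²_C(M_i) + σ²_E(M_i),
* cross-covariance: σ²_A + σ²_C for MZ pairs, ½σ²_A + σ²_C for DZ pairs,

where each component is log-linear in the moderator,
σ²_X(M) = exp(β₀ₓ + β₁ₓ M).  This marginal form is the exact integral of
the generative hierarchy the simulator draws from: MZ pairs share a familial
effect F_i ~ N(μ + β₁ₘM, σ²_A+σ²_C) with independent unique-environment
noise per twin; DZ pairs combine a shared common-environment effect
C_i ~ N(μ + β₁ₘM, σ²_C) with a genetic value
A3_ij = σ_A·(√½ A1_i + √½ A2_ij) built from a standard-normal family value
A1 and per-twin Mendelian-sampling terms A2, the unique weighting giving
Var(A3) = σ²_A and a DZ co-twin genetic correlation of exactly 0.5
(`twinirt.fit.log_likelihood` evaluates this augmented density; the test
suite verifies by quadrature and Monte Carlo that it integrates to the
collapsed form).

Moderating log variances keeps σ²_X > 0 for any real coefficients and makes
the map (β₀ₓ, β₁ₓ) → (σ²_X(0), σ²_X(1)) injective.  The classical
alternative — moderated paths squared into variances, σ²_X = (b₀+b₁M)² —
admits up to four sign-flipped coefficient pairs with identical fit on a
binary moderator; `purcell_equivalent_solutions` constructs that orbit and
the tests use it as the executable form of the identification contrast.

Heritability is reported at the moderator reference level:
h² = exp(β₀ₐ) / (exp(β₀ₐ)+exp(β₀꜀)+exp(β₀ₑ)).

### Measurement layer

Item responses are Bernoulli given the trait with
P(Y=1) = logistic(a_k(θ − b_k)); difficulties (and discriminations, 1 for
pure Rasch) are fixed known constants, which anchors the latent scale —
joint item calibration is out of scope.  Missing responses drop out of the
likelihood (standard IRT missingness treatment).  The sum-score comparator
replaces this layer entirely: the number-correct score, divided by the
standard deviation of the scores of all twins whose moderator equals 1
(MZ and DZ pooled, both pair members), is treated as a directly observed
phenotype in the identical biometric layer.  A twin with any missing item
response gets a missing phenotype rather than a partial sum, since a
partial sum is on a different scale; such twins are integrated over rather
than dropped.

## Priors

Normal(0, 10²) on μ and β₁ₘ; Normal(0, 2²) on each of the six log-variance
coefficients — wide on the log-variance scale while keeping exp() finite;
Beta(1, 1) on the zygosity-specific moderator probabilities π_mz, π_dz used
for latent-Bernoulli imputation of missing moderators.  All are
configurable through `PriorSpec`.  A consequence worth knowing: when a
variance component is weakly identified (small samples, or the A/C split,
which rests entirely on the MZ/DZ covariance contrast), the posterior of
its log-variance *slope* acquires a long tail toward the prior's range and
its posterior mean can sit a few tenths from the maximum-likelihood value
even though the HPD interval comfortably covers truth.  This is posterior
geometry, not sampler error — long-chain runs and the quadrature oracle
give the same means — and it is why parameter-recovery checks read the
variance intercepts on the exp scale.

## Sampler

A collapsed Metropolis-within-Gibbs sampler (`twinirt._kernel.AceKernel`),
shared code-for-code by the IRT and sum-score estimators:

* (μ, β₁ₘ): exact bivariate-normal Gibbs draw (conjugate given the pair
  covariance matrices).
* Six log-variance coefficients: adaptive single-site random-walk
  Metropolis (Robbins–Monro step-size tuning to 44% acceptance during
  adaptation and burn-in), plus one joint Metropolis step whose proposal
  covariance is estimated from the second half of burn-in — this handles
  the strong A/C posterior correlation.
* Latent traits (IRT path only): vectorized random-walk Metropolis per
  twin against the co-twin-conditional normal prior and the Bernoulli item
  likelihood; a twin with a missing phenotype in the sum-score path is
  drawn exactly from the conditional normal.
* Missing moderators: exact Bernoulli draws from the two-point conditional;
  π_mz, π_dz: conjugate Beta updates.

Because the family-level effects are integrated out, the chain mixes well
at short lengths: the defaults (1,000 adaptation, 1,000 burn-in, 3,000
kept draws) give split-R̂ ≈ 1.00 and effective sample sizes in the hundreds
on scenario-scale data, verified against 10× longer two-chain runs.
`McmcConfig.paper_scale()` (5,000 / 50,000 / 25,000, one chain) reproduces
the published protocol for users who want it.  Initialization is
method-of-moments: traits from logit-transformed proportion correct,
variance components from Falconer-style MZ/DZ covariance contrasts per
moderator group.  Chains, replications and datasets all derive from
`numpy.random.SeedSequence` spawning, so every run is bit-reproducible
from one seed.

Correctness is established by oracles rather than trust in the kernel: on
tiny instances the MCMC posterior of μ matches deterministic grid
quadrature over (μ, θ) to within 2%; the collapsed pair likelihood matches
the numerically integrated augmented hierarchy; simulator moments match
the closed-form twin covariances.

## Simulation scenarios

The presets emulate the published simulation studies: 2,000 pairs per
dataset (28% MZ, fixed count, not binomial), binary Bernoulli(0.5)
family moderator, exp(β₀ₐ)=exp(β₀꜀)=0.25, exp(β₀ₑ)=0.5, all true
interaction slopes zero, 40 Rasch items per dataset with difficulties drawn
Normal(+1, 1) (scenario 1, floor compression, positively skewed sum scores)
or Normal(−1, 1) (scenario 2, ceiling).  The moderator main effect has
magnitude 0.7 — it explains 0.1225/1.1225 ≈ 11% of phenotypic variance —
and is oriented so that moderator-1 families lie 0.7 *below* the trait
mean: this is the direction implied by the published sum-score skewness of
the two scenarios, and with it scenario 1 pools to Joanes–Gill skewness
≈ +0.74 (published: 0.722).  The two scenarios' trait-to-bank distances
are mirror images that sum to 2, which pins scenario 2's ensemble skewness
near −0.35; the published −0.526 is a single-dataset realization (the
spread of the three printed skewness estimators implies n ≈ 2,880 — one
dataset's DZ twins) and is not reachable as an ensemble value jointly with
scenario 1's.  The item-count presets (`items20/100/250`) fix 1,000 pairs.

What the simulator does *not* emulate: item missingness patterns of real
cohort data, informative moderator missingness (the optional mask is
MCAR), polytomous items, free discriminations, dominance, sex limitation,
and any genetic correlation between moderator and trait.  Passing tests
therefore demonstrate internal validity of the estimator under the stated
generative model, not robustness to those real-data features.

## Problem sizes used in the automated checks

Analytic calibration is exact and instant.  Skewness is computed at the
full published scale (250 × 2,000 pairs; it is cheap).  The sum-score
bias study uses the published 20 replications of 2,000 pairs.
False-positive control (30 replications) and parameter recovery (20
replications) run at 1,000 pairs × 20 items — the sample size of the
published item-count study, whose conclusion ("20 items suffice") the
recovery check reproduces — with 400–500 adaptation/burn-in sweeps and
1,500–2,500 kept draws, chain lengths validated against much longer runs
as described above.

## Known limitations

* Posterior means of weakly identified log-variance slopes are prior-tail
  sensitive (see Priors); compare HPD intervals, medians, or exp-scale
  summaries across prior settings when samples are small.
* HPD-based zero tests are meaningless for the variance components
  themselves (bounded at zero); replication summaries annotate them as
  non-tests.
* The log-linear moderation is monotone in M by construction; a true
  U-shaped (parabolic) moderation pattern would be missed.
* The moderator is family-level; individual-level moderators are rejected
  at validation.
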