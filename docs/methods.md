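# Methods

## The problem

Neighborhood-level studies of food access and health need the distance
from each neighborhood's population-weighted centroid to its nearest
healthy food store. Two measures exist: the straight-line (great-circle)
distance, computable in bulk for free, and the map-based routed distance,
which is accurate but expensive to query (typically a commercial routing
API with rate limits and terms of service). The straight-line proximity
X\* systematically underestimates the map-based proximity X, and using it
as a covariate in a health-outcome regression is classical covariate
measurement error: the estimated exposure effect is biased.

`proximpute` treats this as a two-phase design. Phase I computes X\* for
all N neighborhoods; Phase II queries the accurate X for a subset of n
neighborhoods (chosen by simple random or county-stratified sampling).
X for the remaining N − n units is multiply imputed, and the analysis
model is fitted to each completed dataset and pooled by Rubin's rules.

## Analysis model

Neighborhood case counts Y with population offset follow a Poisson
log-linear model

    log E(Y | X, Z) = β₀ + β₁ X + β₂ᵀ Z + log(Pop),

so exp(β₁) is an adjusted prevalence ratio per mile of proximity. An
X×Z interaction is available (used, e.g., to let metropolitan and
non-metropolitan neighborhoods have different proximity effects).

## Imputation model and multiple imputation

The conditional law of X given the observed data is modeled as normal
with mean α₀ + α₁X\* + α₂ log(Y) + α₃ᵀZ and standard deviation σ, fitted
by OLS on the queried units (residual scale uses the unbiased n − p
denominator). Including the analysis outcome — as log(Y), matching the
log link — makes the imputation model congenial with the Poisson analysis
model; omitting it attenuates β̂₁ (demonstrated by a directional test).

For each of B = 20 iterations, missing X values are replaced by draws
from the fitted conditional, the Poisson model is fitted to the completed
data, and the B estimates are pooled: point estimate = mean; total
variance T = W̄ + (1 + 1/B)B̂ with W̄ the mean within-imputation variance
and B̂ the between-imputation variance.

Three deliberate choices here:

* **Proper imputation by default.** The imputation-model parameters
  (α, σ) are re-drawn each iteration from their asymptotic sampling
  distribution (normal for α, scaled inverse chi-square for σ²) before
  drawing the missing X. With a Phase-II subset as small as n ≈ 39, the
  estimation uncertainty in α̂ is a material part of the total
  uncertainty; holding α̂ fixed ("improper" imputation, available via
  `proper=False`) underestimates the between-imputation variance and
  produced ~88% empirical coverage for a nominal 95% interval in our
  simulations. Proper imputation restores ASE ≈ ESE and near-nominal
  coverage.
* **t quantiles at B − 1 degrees of freedom by default.** The classic
  Rubin degrees of freedom, (B−1)(1 + W̄/((1+1/B)B̂))², exceed 100 in
  these settings (the between variance is a small share of the total),
  making intervals effectively normal. Using t with df = B − 1 = 19
  widens them by ~7%, a deliberately conservative small-B convention
  whose empirical coverage (~0.97) matches the mildly above-nominal
  coverage this estimator exhibits under the technically misspecified
  normal imputation model (X is gamma plus truncated-normal error, not
  normal). The classic formula is available via `df_method="rubin"`,
  normal quantiles via `use_t=False`.
* **Untruncated draws.** The normal conditional can produce negative
  imputed proximities; draws are left untruncated by default because the
  variance estimator relies on the normal model, with an opt-in
  `truncate_at_zero` clip.

Y = 0 under the log transform raises an error pointing to an explicit
`log1p` opt-in rather than silently shifting.

## Distance computations

Straight-line distances use the haversine formula on a sphere of radius
6,378,137 m (the equatorial radius used by common geodesy toolchains,
overridable), converted to miles by the exact factor 1609.344. Map-based
distances go through a pluggable `DistanceProvider` taking batched
(origin, destination) pairs; individual pairwise routed distances are
never persisted — only the per-neighborhood minimum is kept.

The shortlist rule bounds the number of routed queries: for each
neighborhood only the ⌊M·fraction⌋ stores nearest by straight line
(default fraction 0.2; ties broken by ascending store id) are queried.
Because a routed distance can never be smaller than the straight-line
distance, the routed-nearest store is guaranteed to be inside the
shortlist whenever its routed distance is at most the straight-line
distance of the first excluded store; the shortlist is defined by count,
not by a distance threshold.

## Spatial extension

When bordering neighborhoods are correlated (diagnosed with Moran's I on
the naive-model residuals e\* = Y − Ŷ\*, with the closed-form
randomization-null variance or an optional permutation p-value), the
analysis model gains a neighborhood random intercept r with a proper CAR
prior: r ~ N(0, σ²(D − ρA)⁻¹), A the binary contiguity matrix, D its
degree diagonal. Binary weights are the default; row standardization sits
behind a flag.

Estimation is Laplace-approximate maximum likelihood: for candidate ρ on
a grid inside the valid spectral interval (1/λ_min, 1/λ_max) of
D^(−1/2)AD^(−1/2), σ² is maximized by a bounded one-dimensional search;
the inner (β, r) mode is found by joint penalized Newton with
step-halving (the penalized log-likelihood is monitored and
non-decreasing). Fixed-effect standard errors come from the β block of
the inverse joint Hessian, so they reflect the estimated random field and
are larger than the non-spatial GLM's on positively autocorrelated data.
With σ² constrained to 0 the fit collapses to the ordinary GLM (agreement
to 1e−6 is tested). Published spatial fits of this kind come from
different estimation software; qualitative agreement (recovery of β
within Monte Carlo error, SE inflation) is what the tests assert, not
numerical equality with any external fitter.

## Synthetic data

The generator reproduces the simulation design exactly: X ~ gamma(shape
1, scale 2.5) miles; additive errors U ~ Normal(μ_U = −0.7, σ_U = 0.8)
truncated to [−X, 0] per unit (so 0 ≤ X\* = X + U ≤ X always), or
multiplicative errors W ~ Normal(μ_W = 0.7, σ_W = 0.15) truncated to
[0, 1] with X\* = WX; Pop ~ Poisson(4095), re-drawn in the
measure-zero event Pop = 0; Y ~ Poisson(Pop·exp(β₀ + β₁X)) with β₀ =
−2.2, β₁ = 0.01, giving mean prevalence exp(β₀)/(1 − 2.5β₁) ≈ 11.4% by
the gamma moment generating function. μ and σ are parent-normal
parameters before truncation; truncated draws use the inverse CDF
(exact even for extreme bounds, verified against rejection-sampling
oracles by Kolmogorov–Smirnov distance). Y is an unbounded Poisson draw —
at 11% prevalence Y ≤ Pop in practice but it is not enforced.

The region emulator lays counties out as blocks of a rectangular tract
grid with rook contiguity (the simplest structure in which "bordering"
is well defined), marks the most central counties metropolitan, scatters
stores uniformly, and emulates routed distances by inflating straight
lines with a deterministic pair-specific factor ≥ 1. It makes no attempt
to reproduce any real geography; what passing tests show is that the
estimators behave as designed under the stated error laws, not that any
particular real region satisfies them.

## Simulation engine and problem sizes

Each replicate draws a fresh dataset and runs the four analyses (gold
standard on true X; naive on X\*; complete case on the queried subset;
multiple imputation). Metrics follow the standard table layout: empirical
relative bias (absolute at the null β₁ = 0, where relative bias is
undefined yet tables print 0.000), empirical SE, average estimated SE and
CI coverage (reported for the imputation estimator), and relative
efficiency var(gold)/var(method). Replicates get child seeds spawned from
the master seed, so results are independent of execution order. Any
replicate failing to converge is excluded and counted; a scenario errors
if more than 1% fail.

Full-scale runs use 1000 replicates (`scripts/acceptance.py`); the test
suite runs scaled-down scenarios (100–400 replicates) with Monte Carlo
tolerances widened by 1/√(reps/1000). CAR tests use a 400-tract grid
(25 counties × 16 tracts), the scale at which the Laplace fit is exact
enough for 3-standard-error parameter recovery.

## Known limitations

* The imputation model is normal while the truth (gamma plus truncated
  error) is not; this misspecification is intentional — it mirrors the
  applied setting — and is what makes the conservative-coverage
  convention above relevant.
* The CAR fit is Laplace-approximate with ρ on a grid; no claim of
  equality with MCMC or other mixed-model software.
* No live routing client: map-based distances enter only through the
  `DistanceProvider` contract and the synthetic road-inflation provider.
* Design-based alternatives (IPW, raking), regression calibration,
  maximum likelihood, negative-binomial outcomes, and optimal Phase-II
  designs are out of scope.
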