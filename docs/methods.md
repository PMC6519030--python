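# Methods

## The model chain

The package treats breeding time as a labile, female-expressed trait with a
linear individual reaction norm against the spring cue temperature (the mean
daily temperature over a window such as March 11 – April 20). Three fitted
models and one predictor make up the chain.

**Optimal reaction norm.** The optimal laying date in year *j* is the
caterpillar-peak date minus a rearing lag of 33 days (egg laying to peak
chick food demand: ~9–10 eggs at one per day, 12–13 days incubation, peak
demand at chick age 9–11 days). Missing early peak dates are hindcast from
the peak-versus-cue regression fitted on observed years; hindcasts outside
the calibration temperature range are flagged, not refused. LDθ is
regressed on the cue temperature with period indicators (optionally a
period×temperature interaction); elevations are reported at the grand-mean
temperature so that elevation change is orthogonal to slope change.
Uncertainty comes from a year-resampling bootstrap with BCa intervals
(bias correction from the fraction of replicates below the estimate,
acceleration from jackknife skewness; degenerate distributions return
zero-width intervals with a warning). The bootstrap unit is the year
because LDθ is a yearly quantity; within-period resampling preserves
period sizes.

**Random-regression animal model.** Laying date is Gaussian with fixed
effects (intercept; age class with reference "older" — first-year and
unknown-age offsets estimated; temperature), random year and nest-box
intercepts, individual permanent-environment intercept+slope pairs with an
unstructured 2×2 covariance, and optionally additive-genetic intercept+slope
pairs whose covariance is Σ_G ⊗ A with A the numerator relationship matrix.
Temperature is grand-mean-centred in the animal model; the selection model
uses within-individual centring and then also carries the between-individual
mean temperature as a fixed effect, separating real plasticity from
temperature-correlated composition effects. Residual variances are
heterogeneous across groups of years: years are ranked by cue temperature
and cut into equal-count blocks (default count: number of years / 10,
rounded). Rank-based equal-count grouping (rather than equal temperature
width) guarantees every group has data. A "decade" grouping (consecutive
calendar blocks) and a homogeneous residual are available for the
misspecification experiment.

**Bivariate selection model.** For females with ≥ 2 breeding attempts,
laying date (repeated, Gaussian) and lifetime reproductive success (one
count per female, overdispersed Poisson with log link) are modelled jointly;
each female's (elevation, slope, log-fitness intercept) triple is drawn from
an unstructured 3×3 covariance matrix. The covariance between reaction-norm
components and the fitness intercept is the selection signal. The Poisson
trait's residual variance is held at 0.01 — effectively constrained to zero
while keeping the latent chain mobile. Unknown-identity records are excluded
from both individual-level models (they cannot inform individual effects)
but retained for the annual gradient analysis, where their exclusion would
bias the surface (they over-represent extreme layers).

**Selection gradients and prediction.** Each year's fitness surface is a
penalized B-spline regression (8 basis functions, cubic) of recruit counts
on laying date with log link; the smoothing weight is chosen by the AIC
effective-dof criterion via Nelder–Mead (the GCV attribute of the underlying
GLM results is unreliable, so AIC is the default); NB2 overdispersion is
moment-estimated from a Poisson pre-fit, with a Poisson fallback below
α = 10⁻³. The directional gradient is the unstandardized average-derivative
gradient of relative fitness, β_z = mean W′(z_i)/mean W(z_i), with SEs from
parametric bootstrap (counts redrawn at fitted means, penalty and family
held fixed). Gradients stay on the day scale because the breeder's equation
consumes them against G in day units. Annual genetic change is
Δḡ = G(1, x_j)ᵀ β_zj, multiplied by the next year's recruit fraction
p_recr (generation-time correction; computed as locally born first-year
breeding females over all breeding females) and by 0.5 for sex limitation.
SEs follow first-order propagation with Var of G-terms taken from HPDIs via
the normal approximation (half-width / 1.96)² — a recipe that is
conservative for zero-bound skewed components, which we keep and note.
Cumulative change sums years; its CI half-width is 1.96·√ΣSE².

## Sampler

All Gaussian effects have conjugate Gibbs updates. Two design choices
matter:

1. **Joint individual-effect draw.** For each phenotyped female the
   permanent-environment and additive effects are near-collinear (only the
   pedigree separates them). They are therefore sampled in a single sparse
   Gaussian draw over all breeding values and PE effects, with precision
   blockdiag(kron(A⁻¹, Σ_G⁻¹), kron(I, Σ_PE⁻¹)) + Z′WZ, using the
   perturbation method (solve C θ = r + e with e ~ N(0, C) assembled from
   A⁻¹ = S′S and Σ⁻¹ = B′B) and one sparse LU factorization per iteration.
   Separate block updates leave the PE↔G exchange direction unmixed at any
   chain length.
2. **Parameter expansion.** Covariance blocks are parametrized as
   Λ Ψ Λ′ with unit-scale effects (Ψ ~ IW(df = dim, scale = dim·I)) and a
   diagonal working scale Λ with N(0, 25²) priors updated by a weighted
   regression — the standard expanded prior for variance components that
   are plausibly near zero, where the plain inverse-Wishart Gibbs step
   stalls. The sampler was validated against an exact grid posterior
   (dense multivariate-normal marginal likelihood) on an intercept-only
   animal model.

Scalar variances (year, nest box, residual groups) use weak
scaled-inverse-χ² priors (ν ≈ 1). The Poisson trait's latent log-means use
adaptive random-walk Metropolis plus a joint translation move of
(latent, individual effect) along the direction the fixed 0.01 residual
variance makes stiff. Posterior summaries are medians with 95% HPDIs
(shortest interval); medians because zero-bound variance posteriors are
right-skewed. ESS uses Geyer's initial-positive-sequence estimator. Default
chain lengths (1,300 iterations, 300 burn-in) are desk-scale; the long
reference settings (10⁵ burn-in, thinning 10⁴) are reachable through
`MCMCSettings`.

Numerical details: non-PSD covariance states are repaired by 10⁻⁸ diagonal
jitter with a logged count; a non-finite sampler state aborts with the
iteration number; sparse LU uses minimum-degree ordering in symmetric mode.
A⁻¹ is built by Henderson's rules with inbreeding from the tabular method
(a non-inbred variant is available); the S factor (D^(-1/2)(I−P)) is reused
for exact prior draws.

## The synthetic study

The generator emulates a 44-year nest-box population: fixed plot capacity,
annual adult survival 0.45, vacancies filled by local recruits with
probability 0.6 (else immigrants = new founders), surviving pairs retained
with probability 0.7, and recruits choosing natal broods proportionally to
gamma(1) per-pair weights so that recruitment clusters into full-sib
families of realistic size (1–8). These rates reproduce roughly 3,000
females and 4,900 broods at capacity 110 and give a mean recruit fraction
of ~0.33 (generation time ≈ 2 years). Springs warm at 0.035 °C/year around
6.7 ± 1.2 °C; the food peak follows the cue at −3.15 days/°C with 4-day
residual scatter; the optimum is the peak minus 33. Laying dates assemble
the animal-model equation exactly, with variance components at the
posterior-median values of the motivating system (additive 4.38 day² /
0.02 (days/°C)², PE 3.24 / 0.02, year 9.65, nest box 1.22, residual SDs
3.33–4.39 rising with temperature); founders draw breeding values from
MVN(0, G) and offspring take midparent plus MVN(0, G/2) Mendelian deviations
(non-inbred approximation — the pedigree is shallow, and estimation still
accounts for inbreeding via A). Expected recruits decay as a Gaussian in the
phenotype–optimum mismatch (width 12 days, 1.2 recruits at the optimum),
realized as negative-binomial counts (size 2); a configurable fraction of
broods is flagged manipulated with a multiplicative fitness effect, and a
small fraction of records loses its female identity with probability rising
in |deviation from the mean laying date|.

What the generator does **not** emulate: spatial structure, extra-pair
paternity, density dependence, clutch-size trade-offs, or measurement error
in the food peak. Passing recovery tests therefore demonstrates the
estimators are correct for data with this covariance structure, not that
field estimates are immune to those complications.

## Test-suite problem sizes

Simulation studies run at reduced scale chosen to keep the default suite
near ten minutes: parameter recovery uses 20 datasets of ~1,150 females over
30 years with 900-iteration chains; the misspecification experiment 100
replicates of ~500 females with 700-iteration chains; gradient calibration
200 replicates of 300 broods with 40 bootstrap refits; BCa coverage 200
replicate 30-year series with 1,000 bootstrap draws. The acceptance script
uses one 44-year population at plot capacity 60 (~1,500 females).

## Known limitations

- The PE/G split is weakly identified in shallow pedigrees; its posterior
  is honest (validated against exact posteriors) but wide, and point
  medians can sit far from the truth in unlucky realizations.
- HPDI endpoints from short chains are noisy; unthinned storage is the
  default for interval quality at fixed cost.
- The misspecification experiment's detection criterion (slope contribution
  > 5% of modelled variance with posterior mass > 0.9) is a package
  definition; the denominator includes the mean residual variance so the
  fraction stays stable when both individual components sit at zero.
- Full sliding-window machinery (weighted windows, randomization tests) is
  out of scope; the grid search maximizes plain r² only.
- Error propagation is first-order and treats G-matrix elements as
  independent; the Monte-Carlo check bounds the error at ~10% for realistic
  inputs.
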