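# Methods

## Model

A gene family in a single population starts with `n0 = 2` copies at time 0
(the root duplication, whose time `t₂ = 0` is fixed) and evolves by a
birth–death process: each copy duplicates at constant rate `λ` and is lost
at hazard `μ`, whose shape encodes the retention mechanism — constant `μ`
for nonfunctionalization, `α e^{−tα}` for neofunctionalization, and the
reversed logistic `α e^{γ−t}/(1+e^{γ−t})` for subfunctionalization. Only
copies surviving to the present time `T` are observable, so all quantities
refer to the reconstructed process.

The building blocks are the survival probability
`P(τ,T) = [1 + ∫_τ^T μ_t e^{ρ(τ,t)} dt]^{−1}` with
`ρ(τ,t) = ∫_τ^t (μ_s − λ) ds`, the multiple-descendant probability
`u_{ij} = 1 − P(t_i,t_j)e^{ρ(t_i,t_j)}`, the geometric parameter
`η_{ij} = 1 − (1−u_{iT})/(1−u_{jT})`, and the negative-binomial
lineage-count law `P(n_T=n | n_τ=m) = C(n−1,m−1)(1−η)^m η^{n−m}`.
The conditional density of the i-th duplication time given the previous one
and `(n_T, T)` is

    f(t_i | t_{i−1}, n_T, T) = (i−1) λ P(t_i,T) (1−η_{t_{i−1},t_i})^{i−1}
                               · P(n_T | n_{t_i}=i, T) / P(n_T | n_{t_{i−1}}=i−1, T),

which after cancellation equals
`λ (n_T−i+1) P(t,T)(1−u_{tT}) u_{tT}^{n_T−i} / u_{sT}^{n_T−i+1}` and
integrates to 1 on `(t_{i−1}, T)`.

**Joint density (a deliberate design choice).** The joint density of the
times is implemented as the telescoped product of these conditionals, i.e.
the familiar product form

    ∏_{i=n0+1}^{n_T} (i−1) λ P(t_i,T) (1−η_{t_{i−1},t_i})^{i−1}
      / [ C(n_T−1, n0−1) (1−η_{0,T})^{n0} η_{0,T}^{n_T−n0} ]

**multiplied by** the trailing factor `(1−η_{t_{n_T},T})^{n_T}` — the
probability that none of the `n_T` lineages duplicates again between the
last observed event and the present. Without that factor the product form
does not integrate to 1 and, used as a likelihood on sequentially simulated
data, is misspecified: in a pilot experiment it produced strongly biased
rate estimates (duplication rate estimated near 0.85 when the generating
value was 0.2). With the factor, the joint density is exactly the law the
sequential simulator draws from, maximum-likelihood estimation is
consistent (verified empirically up to `n_T = 300`), and the telescoping
identity joint = ∏ conditionals holds to machine precision (tested). A
timeline with no events (`n_T = n0`) carries log density 0.

**Age-dependent model.** The more biological assumption is that each
duplicate's hazard clock starts at its own birth. The age `t′` of a copy
surviving unduplicated to time `t` has density proportional to
`exp(−(λ t′ + ∫_0^{t′} μ_a da))` on `(0, t)` — the no-event probability of
a Poisson process with intensity `λ + μ_age`, with the hazard evaluated at
copy age (the inner integral runs over age, not absolute time; this
resolves an ambiguity in the definition in favor of the birth-clock
reading). The model then closes the hierarchy by replacing each copy's
random hazard with its expectation, the mean loss rate
`φ_t = ∫_0^t μ_{t′} f(t′) dt′`, and substituting `φ` for `μ` in *every*
downstream quantity (`P`, `ρ`, `u`, `η`, densities). This mean-field
(moment-closure) substitution is a model definition here, not an
approximation theorem. With a constant hazard `φ ≡ μ` and the age model
reduces exactly to the time model (asserted across the API in the tests).

## Parameters, units, defaults

Time units are arbitrary; all rates are per unit time.

| parameter | meaning | default / admissible range |
|---|---|---|
| `λ` | per-copy duplication rate | study value 0.2; fits bounded to `[1e−4, 20]` |
| `μ` | constant loss rate (nonfunc) | study value 0.8; fits bounded to `[1e−4, 20]` |
| `α` | hazard scale (neo/sub) | study value 0.8; constrained to `(0, 1)` |
| `γ` | logistic location (sub) | fixed 5.0, never estimated |
| `T` | present time | 10 |
| `n0`, `n_T` | copy counts at 0 and T | 2 and 32 (studies also use 100) |

`γ = 5` makes the subfunctionalization hazard at age 0 equal `α` to within
1 %, so all three mechanisms share the same initial deletion rate and
differ only in hazard *shape* — the matched-onset design
(`duplifate.standard_mechanisms()`). The true `γ` of a dataset is treated
as known; estimating it is out of scope.

## Numerical choices

- **Quadrature.** The survival integral is evaluated two ways: the public
  scalar `survival_prob` uses deterministic adaptive quadrature
  (`scipy.integrate.quad`, rel. tol 1e−10), with a seeded Monte Carlo
  estimator kept as an option and cross-checked in the tests. Likelihoods,
  conditional densities and the simulator use a vectorized panel
  Gauss–Legendre rule over the segments between the query times: the
  integrand factors as `μ_t e^{E(t)}` with `E(t) = ∫_0^t μ − λt`, so one
  sweep serves every query point. Panels are subdivided to well under one
  e-folding of the integrand; agreement with the adaptive route is asserted
  at 1e−8.
- **Log space everywhere.** `log(1−u) = log P + ρ` is the workhorse;
  powers of `1−η` telescope into differences of it, and `u` is recovered via
  `expm1`, never as `1 −` a near-one float. Exponentials are shifted by
  their running maximum before summation.
- **Closed-form cumulative hazards** (constant, exponential, softplus form
  for the logistic) back the time-dependent model; the age model integrates
  its `φ` interpolant.
- **φ cache.** `φ_t`'s numerator and normalizer are cumulative integrals of
  fixed functions of age, so one panel-quadrature sweep tabulates `φ` on a
  256-point grid (log-spaced near 0 where it varies fastest); a monotone
  PCHIP interpolant and its antiderivative serve rate and integral queries.
  Interpolated values match direct nested quadrature to rel. 1e−4
  (tested), and survival probabilities are stable under grid refinement.
- **Rejection sampler.** Each next duplication time is drawn under a flat
  envelope: coarse 128-point scan of the conditional density, two local
  refinement sweeps (extending to the open interval ends, where the density
  may peak), times a 1.05 safety factor. A proposal exceeding the envelope
  triggers a rebuild with factor 1.5 and a logged warning; the proposal
  budget is 10⁶ per event. Draws are deterministic given the generator
  state; replicate studies spawn one child stream per replicate from the
  master seed.
- **Optimizer.** Likelihoods are maximized by Nelder–Mead from five fixed
  starts on transformed scales (`log λ`, `log μ` or `logit α`), bounded by
  clipping; the best optimum wins, making fits deterministic. A seeded
  random-walk Metropolis–Hastings refinement pass (`refine="mh"`) is
  available as the stochastic alternative. Standard errors in fit summaries
  come from the finite-difference observed information.
- **Ties and degenerate inputs.** AIC ties break in the fixed order
  nonfunc < neo < sub; non-convergent fits are excluded from selection but
  still reported. A single duplication time is fittable (with wide
  uncertainty); an empty timeline is not. Ensemble standard errors with one
  replicate are reported missing with a warning.

## Simulation studies and problem sizes

The generator reproduces the conditional study design: timelines simulated
given `(T = 10, n_T)` at the matched-onset parameters, `t₂ = 0`, events
drawn sequentially. The identification study simulates under each
mechanism, fits all three, and selects by lowest AIC (`k = 2` for every
mechanism since `γ` is fixed); the default acceptance run uses 30
replicates per mechanism at `n_T = 32` (time model) and 20 replicates at
`n_T = 100` (age model, subfunctionalization truth), sizes chosen to give
roughly ±5 and ±9 percentage-point binomial resolution at modest runtime.
The standard-error study uses 30 replicates at sample sizes 20 and 100.
Ensemble standard errors are the standard deviation of the MLEs across
replicates — the natural definition for a simulation study.

What the generator does *not* emulate: real gene families with sequence
data (duplication times are taken as directly observed), tree topology,
loss times, multiple species, population-genetic effects, and gene families
evolving under mixtures of mechanisms.

## Known limitations

- Identification percentages depend strongly on the study geometry: with
  only ~30 highly autocorrelated event times per family the three fitted
  likelihoods often differ by well under one log unit, so the per-family
  selection signal is weak, and `λ` is only weakly identified when the
  analysis conditions on `(T, n_T)`. The neofunctionalization `α` is
  especially poorly pinned down (its hazard has decayed to near zero over
  most of the observation window), and its estimate frequently lands on the
  `(0,1)` boundary.
- MLEs carry a small finite-sample bias at `n_T = 100` (about +0.05 on `λ`)
  that vanishes by `n_T = 300`.
- The mean-field `φ` substitution ignores fluctuations of copy ages around
  their common age distribution; the exact age-structured likelihood that
  tracks every copy's birth time is out of scope.
- The likelihood conditions on surviving copies only; duplicates lost
  before the present contribute no information and no correction for that
  selective observation is attempted beyond the reconstructed-process
  conditioning itself.
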