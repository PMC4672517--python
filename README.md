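# duplifate

Birth–death modeling of the fates of gene duplication: simulate duplication
times of surviving gene copies under competing retention mechanisms, evaluate
the reconstructed-process likelihood, fit mechanisms by maximum likelihood,
and discriminate them with AIC.

## The scientific problem

After a gene duplicates, the redundant copy is usually silenced and lost
(**nonfunctionalization**), but it can be retained — either by acquiring a
beneficial new function (**neofunctionalization**) or because complementary
degenerative mutations split the ancestral function across both copies
(**subfunctionalization**). Each mechanism leaves a distinct fingerprint on
the *hazard* (instantaneous loss rate) of a duplicate as a function of time
or copy age:

| mechanism | hazard of copy loss | parameters |
|---|---|---|
| nonfunctionalization | `μ(t) = μ` (constant) | `μ > 0` |
| neofunctionalization | `μ(t) = α e^{−tα}` (convex decay) | `0 < α < 1` |
| subfunctionalization | `μ(t) = α e^{γ−t} / (1 + e^{γ−t})` (sigmoid decay) | `0 < α < 1`, location `γ` fixed |

Duplications occur at a constant per-copy rate `λ`. Because extinct copies
are unobservable, the package works with the *reconstructed* birth–death
process: starting from two copies at the root (`t₂ = 0`), the ordered
duplication times `t₃ < … < t_{n_T} < T` of the `n_T` copies surviving to
the present `T` have joint density built from

- `P(τ, T) = [1 + ∫_τ^T μ_t e^{ρ(τ,t)} dt]^{−1}`, the probability a copy at
  `τ` leaves surviving descendants, with `ρ(τ,t) = ∫_τ^t (μ_s − λ) ds`;
- `u_{ij} = 1 − P(t_i,t_j) e^{ρ(t_i,t_j)}` and
  `η_{ij} = 1 − (1−u_{iT})/(1−u_{jT})`, the reconstructed-process
  branching probabilities;
- a negative-binomial lineage-count distribution
  `P(n_T = n | n_τ = m) = C(n−1, m−1) (1−η)^m η^{n−m}`.

Two model kinds are provided. In the **time-dependent** model every copy's
hazard clock starts at the root. In the **age-dependent** model each copy's
clock starts at its own birth; the random per-copy hazard is replaced by its
expectation `φ_t` over the age distribution of copies surviving at `t`
(a mean-field closure), and `φ_t` substitutes for `μ_t` throughout.

Timelines are simulated *conditionally* on `(T, n_T)` by sequential rejection
sampling from the exact conditional density of each next duplication time.
Mechanisms are fitted by maximizing the joint log density over `(λ, μ)` or
`(λ, α)` (with `γ` fixed), and compared by `AIC = 2k − 2 log L` with `k = 2`.

## Worked example

Simulate one gene family (30 duplication times conditional on `T = 10`,
`n_T = 32`) under nonfunctionalization with `λ = 0.2`, `μ = 0.8`, then fit
and select the mechanism:

```python
import numpy as np
from duplifate import MechanismParams, SimConfig, simulate_timeline, fit_mle, model_select

params = MechanismParams.nonfunctionalization(lam=0.2, mu=0.8)
cfg = SimConfig(params=params, model="time", T=10.0, n0=2, nT=32, seed=6)
tl = simulate_timeline(cfg, np.random.default_rng(6))
print(fit_mle(tl, "nonfunctionalization", model="time").summary())
print(model_select(tl, model="time").summary())
```

```
Duplicate retention model fit
==============================================
mechanism:       nonfunctionalization
model kind:      time-dependent
n events:        30  (n0=2, nT=32, T=10)
log-likelihood:  34.2545
AIC (k=2):       -64.5090
converged:       True   (nfev=635)
----------------------------------------------
param         estimate     std err
lambda         0.20858     0.50999
mu             0.81321     0.32276
==============================================
selected mechanism: nonfunctionalization
----------------------------------------------
nonfunctionalization     AIC =    -64.509
neofunctionalization     AIC =    -64.360
subfunctionalization     AIC =    -64.374
```

The MLEs `(λ̂, μ̂) = (0.209, 0.813)` recover the generating values
`(0.2, 0.8)`; the large standard errors reflect how weakly a single
32-copy family constrains the rates (the observed times are few and highly
autocorrelated). All three candidate AICs are close, but the true mechanism
wins on this replicate.

The same pipeline is available from the shell:

```bash
duplifate simulate --mechanism nonfunctionalization --model time \
    --lambda 0.2 --mu 0.8 --T 10 --n0 2 --nT 32 --reps 100 --seed 1 --out times.tsv
duplifate select times.tsv --model time --out selection.json
duplifate study-identify --model time --nT 32 --reps 30 --seed 1
duplifate study-se --mechanism nonfunc --sizes 20,60,100 --reps 30 --seed 1
```

Every output file gets a `.meta.json` sidecar (resolved configuration,
package version, seed) from which it can be regenerated exactly.

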