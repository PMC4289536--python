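# streamide

Integrodifference models for population persistence in rivers and
streams — habitats where everything is constantly washed downstream,
yet populations persist (the *drift paradox*).

`streamide` is for ecological modellers who want quantitative answers
to questions like: below what flow velocity can a benthic population
persist in a 20-km reach?  How long must a reach be before the
population is self-sustaining?  Does year-to-year variability in flow
help or hurt?

## The model

The population grows and disperses in discrete annual steps on a
habitat `Ω = [x₀, y₀]`:

    n_{t+1}(x) = ∫_Ω K_t(x − y) f_t(n_t(y)) dy.

Dispersal is by advection `v`, diffusion `D`, and settling at rate `β`,
which makes `K` an asymmetric Laplace kernel with upstream decay rate
`a₁ = v/2D + sqrt(v²/4D² + β/D)` and downstream rate
`a₂ = v/2D − sqrt(v²/4D² + β/D)`.  Individuals that settle outside `Ω`
are lost.

Persistence is decided by a growth metric being above or below one:

| environment | metric | solver |
|---|---|---|
| constant | principal eigenvalue `λ₁` of the linearized operator | Nyström quadrature and an equivalent 2nd-order boundary-value problem |
| alternating (two kernels) | two-step eigenvalue `λ₁,twostep ≤ R₁R₂` | composite Nyström and a 4th-order boundary-value problem `det A(λ) = 0` |
| random i.i.d. | asymptotic growth rate `Λ = lim (∫n_t)^{1/t}`, equal to the generalized spectral radius `r = lim ‖L_t⋯L₁‖^{1/t}` | seeded Monte-Carlo iteration, operator-norm products, and an exact exponential-sum formula for `Λ_t` |

Setting `λ₁,twostep = 1` and solving for the habitat length gives the
critical domain size `L_c`; the flow velocity at which `L_c` diverges
is the root of the closed-form condition `min_s R₁R₂ M₁(s)M₂(s) = 1`
on the kernels' moment generating functions.  The nonlinear model with
Beverton–Holt growth exhibits the persistence/extinction dichotomy the
linear metrics predict.

## Worked example

```python
import numpy as np
from streamide import (Habitat, StageParams, derive_rates, build_nystrom,
                       principal_eigenpair, eigen_bvp_single, CoinFlipSpec,
                       estimate_Lambda, TwoStageProblem, twostep_eigenvalue,
                       critical_velocity)

h = Habitat(0.0, 20.0, 801)                       # a reach of length 20
st = StageParams(derive_rates(0.95, 1.0, 1.0), 1.2)  # v=0.95, D=beta=1, R=1.2
lam = principal_eigenpair(build_nystrom(st, h), h)
print(f"single-kernel lambda1 (v=0.95): {lam.lambda1:.4f}"
      f"  (BVP: {eigen_bvp_single(st, h).lambda1:.4f})")

slow = StageParams(derive_rates(0.1, 1.0, 1.0), 1.2)   # low-flow year
fast = StageParams(derive_rates(1.0, 1.0, 1.0), 1.5)   # high-flow year
alt = twostep_eigenvalue(TwoStageProblem(slow, fast, h))
print(f"alternating two-step lambda: {alt.lambda1:.4f}"
      f"  (annual rate {alt.lambda1**0.5:.4f})")

est = estimate_Lambda(CoinFlipSpec(slow, fast), Habitat(0.0, 20.0, 401),
                      T=5000, replicates=8, seed=1)
print(f"coin-flip Lambda: {est.value:.4f} +/- {est.se:.4f}")

vstar = critical_velocity(slow, lambda v: StageParams(derive_rates(v, 1.0, 1.0), 1.5),
                          (1.0, 5.0))
print(f"critical high-flow velocity: {vstar:.3f}")
```

prints

```
single-kernel lambda1 (v=0.95): 0.9629  (BVP: 0.9628)
alternating two-step lambda: 1.5108  (annual rate 1.2291)
coin-flip Lambda: 1.2281 +/- 0.0001
critical high-flow velocity: 2.975
```

Read: at the constant mean flow `v = 0.95` the population dies out
(`λ₁ < 1`), but if low-flow years (`v = 0.1`, growth 1.2) and high-flow
years (`v = 1.0`, growth 1.5) alternate — or are drawn by coin flip —
the effective annual growth rate is about 1.23 and the population
persists.  Variability rescues a population that the average
environment would wash out.  If the high-flow velocity approaches 3,
however, no reach of any length can sustain the alternating
population.

A CLI mirrors the library:

```bash
streamide eigen --v 0.95 --length 20
streamide twostep --v1 0.1 --v2 1.0 --r1 1.2 --r2 1.5
streamide critical-length --v1 0.1 --v2 1.0 --v2 2.0 --v2 2.5
streamide stochastic --kind coinflip --steps 5000 --replicates 8 --seed 1
streamide run path/to/config.yaml      # YAML-configured experiments
streamide reproduce fig6               # sweep drivers emit CSV tables
```

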