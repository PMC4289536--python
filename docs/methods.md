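# Methods

`streamide` computes persistence metrics for populations that grow and
disperse in bounded habitats with unidirectional flow — the classic
"drift paradox" setting of stream and river ecology.  This note records
the models, the numerical choices behind each solver, and the limits of
what the test suite demonstrates.

## Model

The population is unstructured and follows a discrete-time,
continuous-space integrodifference recursion on a habitat
`Ω = [x0, y0]` of length `L`:

    n_{t+1}(x) = ∫_Ω K_t(x − y) f_t(n_t(y)) dy,

with no immigration from outside `Ω` (dispersers crossing the boundary
are lost).  Growth `f_t` acts locally; dispersal is governed by the
kernel `K_t`.

### Dispersal kernel

An individual drifts by advection `v`, diffuses with coefficient `D`,
and settles at rate `β`.  Integrating the settling flux over all time
gives an asymmetric Laplace density in the displacement `u = x − y`:

    K(u) = A e^{a1 u} (u < 0),   A e^{a2 u} (u ≥ 0),
    a_{1,2} = v/(2D) ± sqrt(v²/(4D²) + β/D),
    A = β / sqrt(v² + 4βD),

so `a1 > 0 > a2` and `∫K = 1` on the whole line.  `v = 0` recovers the
symmetric Laplace kernel with rate `sqrt(β/D)`.  The kernel is a pure
difference kernel: individuals do not react to the habitat boundary,
they simply fail to settle inside it.  The value on the diagonal
`x = y` is taken as `A` (the downstream branch); this is a measure-zero
convention.

Derived functionals, all in closed form via the kernel's piecewise
antiderivative: the dispersal success function `s(y)` (probability of
settling inside `Ω` from `y`), the redistribution function `r(x)`
(expected density at `x` after a uniform unit release), and the moment
generating function `M(s) = β/(β + v s − D s²)`, finite for
`s ∈ (a2, a1)`.  The sign convention — positive `s` weights upstream
displacements — makes the upstream pole sit at `a1`; it is fixed here
because it is easy to get wrong silently.  Note that for a difference
kernel with unit whole-line mass the redistribution function is in fact
bounded by 1 (its integral against `dy` is the same whole-line mass);
boundedness is simply not *required* by the theory, and `r ≠ s` once
`v ≠ 0`.

### Persistence metrics

* **Constant environment.**  The linearized operator
  `(Lϕ)(x) = R ∫ K(x−y) ϕ(y) dy`, `R = f'(0)`, is positive and compact;
  its principal eigenvalue `λ₁` (Krein–Rutman) decides persistence
  (`λ₁ > 1`).  Dispersal loss forces `λ₁ < R` on any bounded habitat.
* **Alternating environment.**  Two stages applied in alternation
  compose to a single positive operator with growth factor `R₁R₂` and
  kernel `∫ K₂(x,y) K₁(y,z) dy`; its eigenvalue `λ_{1,twostep} ≤ R₁R₂`
  decides persistence over the two-year cycle.
* **Random environment.**  With i.i.d. draws of `(K_t, R_t)` the
  persistence metric is the asymptotic growth rate
  `Λ = lim (∫ n_t)^{1/t}` of the linearized iteration, equal to the
  generalized spectral radius `r = lim ‖L_t ⋯ L_1‖^{1/t}`; the
  population persists when the common value exceeds one.

## Numerical methods

### Quadrature and the Nyström route

Integral operators are discretized by Nyström collocation with
composite Simpson weights on a uniform grid (node counts odd).  The
kernel has a derivative kink on the diagonal; a uniform grid keeps the
kink on nodes, which preserves stability but reduces Simpson to
observed order 2 in the eigenvalue.  The measured error at grid
spacing `h = 0.025` (n = 801 on L = 20) is about `8×10⁻⁵` relative;
tests that demand `10⁻⁴` cross-route agreement use `h = 0.0125`.
The dominant eigenpair is found by power iteration from the constant
function (which keeps iterates positive), Rayleigh-quotient estimate,
tolerance `1e−10`, with a dense eigendecomposition fallback; the
two-stage radius applies the two factor matrices in sequence instead of
forming their cubic-cost product.

### Boundary-value-problem routes

Because the kernel is the Green's function of
`(D/β) k'' − (v/β) k' − k = −δ`, the eigenfunction equation converts to
a linear ODE with constant coefficients: second order for one kernel
(Robin conditions `ϕ'(x0) = a1 ϕ(x0)`, `ϕ'(y0) = a2 ϕ(y0)`), fourth
order for the alternating pair, whose characteristic quartic in `r` is

    r⁴ − B r³ − (β₁/D₁ + β₂/D₂ − v₁v₂/(D₁D₂)) r² + C r
        + (β₁β₂/(D₁D₂))(1 − R₁R₂/λ) = 0,

with `B = v₁/D₁ + v₂/D₂` and `C = (v₁β₂ + β₁v₂)/(D₁D₂)`, plus four
boundary conditions coupling `ϕ` up to its third derivative at both
ends.  Eigenvalues are roots of the boundary determinant `det A(λ)`.

Numerical choices here:

* the characteristic roots are classified as real, complex-conjugate,
  or near-repeated (within `1e−8` relative), and a real basis is built
  per case (`e^{rx}`; `e^{px}cos qx`, `e^{px}sin qx`; confluent
  `x^j e^{rx}`), so the determinant is real arithmetic throughout;
* every basis function is damped by `e^{−max(0, Re r)·L}` and columns
  are normalized by positive scalars before the determinant, so domains
  of several hundred lengths do not overflow;
* the λ-scan brackets ±20% around the Nyström radius (fallback: a
  400-point scan of `(0, R₁R₂]`), bisecting sign changes between
  scan points of equal root-structure signature; intervals whose
  endpoints differ in structure are refined recursively, since a root
  can sit next to a real↔complex transition;
* the largest root is returned as the principal eigenvalue, with the
  reconstructed eigenfunction checked for positivity (a sign-changing
  reconstruction raises a warning rather than an error);
* a BVP–Nyström disagreement beyond 1% is treated as an assembly bug
  and raised, never returned.

The critical domain length exploits the fact that at `λ = 1` the
quartic roots do not involve `L`: `L_c` is the first root in `L` of the
fixed-basis determinant, refined by bisection to `1e−10`, with an
optional verification that the eigenvalue crosses one upward there.
When the infinite-domain growth factor `min_s R₁R₂ M₁(s) M₂(s)` is at
most one no habitat length suffices, and the sentinel `inf` is
returned; the velocity at which that factor crosses one is the
asymptote of `L_c` and is located by root-finding on the closed-form
moment generating functions.

### Stochastic iteration

`iterate_linear` renormalizes the state to unit mass each step and
accumulates log mass, so arbitrarily long horizons neither underflow
nor overflow; `Λ_t` follows by construction.  `estimate_Lambda`
averages `exp(mean log-increment)` over replicates whose RNG streams
are spawned from one master seed (step-major draw order), so results
are reproducible and — usefully for monotonicity comparisons — two
parameter settings run under the same seed share their underlying
normal draws.  Defaults `T = 5000` and 8 replicates are deliberately
generous because convergence of `Λ_t` is slow, roughly `O(1/t)`.

The operator-norm route forms the product of the per-step matrices
with per-step rescaling and reports the `t`-th root of the norm induced
by the sup norm (maximal weighted row sum) or, optionally, by total
mass (L¹); both share one limit.  For a constant environment the
product is a matrix power and is computed by binary exponentiation,
which is what makes `t ≈ 8×10³` (needed for `O(1/t)` convergence to
`10⁻³`) affordable.

### Exact exponential-sum recursion

Starting from a uniform density, applying an asymmetric Laplace kernel
to a term `p(x) e^{r x}` (polynomial `p`) yields, in closed form, the
same rate `r` plus boundary contributions at the kernel's own rates
`a1` (right endpoint) and `a2` (left endpoint).  After `t`
non-repeating steps the density is a constant plus `2t` exponentials,
and `Λ_t` follows from the closed-form integral — on a centered domain
this is the familiar `L ρ₀ + 2Σ (ρ/a) sinh(aL/2)` combination, but the
antiderivative form used here is translation-invariant, so `[0, L]` and
`[−L/2, L/2]` agree identically.

When a kernel repeats (a coin-flip environment), the generic update has
a vanishing divisor `r − a_i`; rates within `1e−10` relative are merged
and the confluent branch multiplies by `x` instead, raising the
polynomial degree by one.  This keeps repeated environments exact
rather than perturbed.  The recursion is exact in real arithmetic but
numerically fragile: coefficients carry small divisors whose rounding
errors compound, and in double precision the computed `Λ_t` degrades
into noise around `t ≈ 20`.  `exact_lambda_series` therefore runs the
quadrature iteration on the same draws and flags any step where the two
disagree by more than 1% as unstable instead of returning it silently;
a mass that cancels to a non-positive value raises.

### Nonlinear simulation

The persistence/extinction dichotomy for the nonlinear stochastic model
requires growth functions that are increasing, bounded, with strictly
decreasing per-capita growth approaching slope `R` at zero.
Beverton–Holt growth `f(u) = R u/(1 + c u)` satisfies all of them and
is the canonical family here (`c` in units of 1/density, default 1);
`check_conditions` audits the requirements numerically on a log-spaced
grid, and a Ricker map is included as a deliberately rejected
non-monotone example.  Because the dichotomy is a distributional
statement, the tests assert it statistically: five seeds, mass
threshold `1e−8`, time-averaged mass bounded away from zero in the
supercritical case.

## Study conditions and scaling

The recurring parameter set mirrors the worked examples throughout:
`D = β = 1`, `Ω = [0, 20]`, a low-flow stage `v = 0.1, R = 1.2` and a
high-flow stage `v = 1.0, R = 1.5`; the continuous environment draws
`v` log-normally with the mean and variance specified for `v` itself
(moment matching `σ² = ln(1 + ν/m²)`, `μ = ln m − σ²/2`).  Headline
estimates use `T = 5000` with 8 replicates on a 401-node grid; the
monotonicity sweeps in the test suite use `T = 1500` with 3 replicates
on a 201-node grid, which is ample because shared seeds couple the
compared runs.  These sizes were chosen so the full suite runs in a few
minutes while leaving each assertion's tolerance several standard
errors wide.

## What the synthetic environments do and do not capture

All inputs are model parameters; there is no field data.  The random
environments are i.i.d. by construction, so the package demonstrates
nothing about temporally autocorrelated flows (where variability can
harm rather than help persistence), spatially heterogeneous habitats,
or kernels whose parameters covary with growth rates beyond the finite
atom sets modeled here.  The lognormal velocity distribution also
violates the uniform positive lower kernel bound that the persistence
dichotomy's hypotheses formally require (arbitrarily large `v` makes
the kernel arbitrarily small inside `Ω`); the sampler is deliberately
not truncated, matching how the framework is applied in practice, and
the simulations show no pathology — but the theoretical guarantee is
strictly for compactly supported parameter ranges.

## Known limitations

* Composite Simpson on the kinked kernel is order 2, not 4; achieving
  `10⁻⁴` eigenvalue accuracy needs `h ≲ 0.0125` in these units.
  The BVP routes are analytic in `λ` and serve as the high-accuracy
  reference.
* The exact exponential-sum formula is a short-horizon tool by nature;
  beyond `t ≈ 20` in double precision its output is flagged, not fixed.
  High-precision arithmetic would extend the horizon but is out of
  scope.
* `critical_domain` reports the smallest determinant root in `L`; the
  optional monotonicity check guards against a subdominant root being
  picked up, at roughly triple the cost.
* Only two-stage alternation is implemented; `n`-periodic kernel
  chains and analytic critical-length formulas are not.
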