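# Numerical methods and conventions

## Model class

A model couples per-capita growth of strategy-indexed (sub)populations, an
ODE environment component `e1`, an implicitly defined environment component
`e2`, and an autonomous stochastic driver `θ`:

```
dn_i/dt = f(x_i, e, θ) n_i
de1/dt  = G1(e, θ) + Σ_j H1(x_j, e, θ) n_j
e2      = G2(e, θ) + Σ_j H2(x_j, e, θ) n_j     (solved every step)
dθ      = A(θ) dt + B(θ) dW                    (Itô)
```

Structured models carry class-abundance vectors per strategy and an `ℓ×ℓ`
transition-rate matrix `F(x, e, θ)` in place of `f`; the impacts `H1, H2`
return per-class rows contracted against the class vector.

## Simulation

- Populations and `e1` are stepped by forward Euler; `θ` by Euler–Maruyama.
- Noise comes from a counter-based Philox generator keyed by the seed, one
  draw per step, so two simulations sharing seed, step size and driver
  dimension share a noise path regardless of how the populations are
  parameterized (the basis of the dimorphic change-of-variables check).
- `e2` is re-solved each step: a single evaluation when the right-hand side
  does not depend on `e2`, otherwise a damped fixed-point iteration with a
  root-solver fallback.
- Structured populations are integrated as (total size, class distribution)
  pairs; the distribution is renormalized onto the simplex each step and the
  largest renormalization is reported. A raw class-abundance integrator is
  kept as a cross-check.
- Populations are clipped at zero (counted), and any state exceeding an
  overflow guard raises an error.

## Invasion fitness

The fitness of a rare mutant `y` in the environment set by resident `x` is
always computed as the time average of the mutant's per-capita growth rate
along the resident attractor — never by simulating the mutant's
exponentially growing or vanishing population size.

- `ergodic`: one simulated resident trajectory (burn-in discarded); the
  mutant growth rate is averaged along it with a batch-means standard
  error (30 batches). For structured models the mutant's class
  *distribution* is integrated along the trajectory and the instantaneous
  growth rate of its total size is averaged, which converges to the
  dominant growth rate.
- `periodic`: for deterministic models, the resident is integrated to its
  attractor with a high-accuracy adaptive solver (relative tolerance
  1e-10); the period is estimated from upward crossings of the
  post-transient mean of the first population coordinate (linear
  interpolation, coefficient-of-variation guard), then the mutant growth
  rate is averaged over one period by trapezoidal quadrature on 4000 nodes.
- `equilibrium`: the growth rate evaluated at the deterministic fixed
  point.
- `closed_form`: a model-supplied exact formula, when available.

Selection gradients and the second-order coefficient matrices
`C11 = ½ ∂²s/∂x²`, `C22 = ½ ∂²s/∂y²`, `C21 = ½ ∂²s/∂y∂x`, `C12 = C21ᵀ` of
the two-argument fitness `s(x, y)` are computed by central differences.
For stochastic methods, all stencil evaluations share frozen resident
trajectories (common random numbers), which removes most of the
finite-difference noise. The conservation law `C11+C22+C12+C21 = 0`
(a consequence of selective neutrality `s(x, x) = 0`) is reported as a
`conservation_defect` diagnostic, not imposed.

## Classification of similar-pair invasions

For a similar pair `x_i = x + ε ξ_i` the invader frequency `P` follows, on
the appropriate slow clock, an averaged scalar ODE. Three statistics decide
the regime:

- `drive1 = ∇s·(ξ2−ξ1)` — nonzero: directional selection, invasion implies
  substitution (logistic frequency flow).
- `quad = (ξ2−ξ1)ᵀ(C22+C11)(ξ2−ξ1)` — decides the generic second-order
  regime with four cases: substitution either way, protected coexistence
  with interior equilibrium `p* = S12/(S12+S21)`, or mutual exclusion with
  bistable boundaries.
- `mixed = (ξ2+ξ1)ᵀ(C22+C21)(ξ2−ξ1)` — the special second-order regime,
  again substitution.

A dead band `tol` stands in for the strict inequalities; any fitness value
inside the band yields `undetermined`, and sign patterns inconsistent with
the active regime are flagged rather than silently classified. The
slow–fast check simulates the dimorphic pair out to slow time
`T / (drive · ε)` (order 1) or `T / (drive · ε²)` (order 2) over several
seeds and compares `sup |P − p*|` on the second half of the window with a
user tolerance.

## Example-model conventions

- **chemostat** — strategy `(β, γ, δ)`; growth `γβe1 − δ − D`; resource
  inflow `ρ1 − 2ρ2 θ/(1+θ²)` with an OU driver; resource consumption enters
  the environment ODE as `−β e1` per unit population (per-capita uptake
  mass balance). Closed form: `S_x(y) = γ'β' (δ+D)/(γβ) − δ' − D`.
- **lotka_volterra** — the environment *is* the vector of population sizes
  of a finite community with fixed strategies (`community_strategies`), so
  `e2 = n`; simulating residents other than the bound community raises an
  error instructing a rebuild. The closed-form fitness is
  `r(y) · ρ · (1 − α(x→y) K(x)/K(y))` with the OU moment prefactor
  `ρ = exp(ρ1²b²/(4a))` (exact for a stationary OU process,
  `E[e^{ρ1 θ}] = exp(ρ1²b²/(4a))`) and the competition kernel applied with
  the *resident as first argument* (the effect of an `x` individual on a
  `y` individual). These two conventions — selectable via
  `prefactor_mode` and `arg_order` — are the only combination that
  reproduces all published reference fitness values for this model to every
  printed digit; neither choice affects the sign of the fitness.
- **sirs** — two infection-history classes (infected, recovered) per viral
  strategy; susceptibles `S = e1` follow the environment ODE and total host
  density `M = e2` is implicit (`M = S + Σ` classes). The small-noise
  fitness linearizes the resident system at its endemic equilibrium, solves
  a continuous Lyapunov equation for the stationary covariance of
  `(S, M, θ)`, and corrects `S/M` by `½ tr(H Cov)` with `H` the exact
  Hessian of `e^{ρ1θ} S/M`.
- **prey_predator** — deterministic; predators are eliminated adiabatically
  into the implicit component, giving a prey–resource system whose interior
  equilibrium loses stability through a Hopf bifurcation as prey timidity
  decreases. The Hopf point is located by continuation of equilibrium root
  solves plus bisection on the maximum real part of the Jacobian
  eigenvalues.

## Known discrepancies with published reference values

Recomputed values are solver-independent (cross-checked against
independent integrators and step-size sweeps), so the following published
values are believed to carry transcription or rounding artifacts; the
acceptance tests keep the published tolerances and fail honestly:

- Hopf point: converged value 0.62983 vs published 0.6289 (4 d.p. test
  fails; 2 s.f. agreement).
- Period-averaged fitness of the mutual-invasion pair (mutant 0.4314 in
  resident 0.3764): converged 0.0002565 vs published 0.000277 (7.4%
  relative error; the other three pair values agree within 1.3%).
- SIRS small-noise fitness: the literal equilibrium+Lyapunov formula gives
  ±0.00718 vs published ±0.00709 (1.3%); direct stochastic simulation of
  the resident supports the published magnitude being itself an
  approximation, but no literal reading tested reproduces the printed
  third significant figure.
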