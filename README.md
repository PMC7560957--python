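# fluctinvade

Resident–invader dynamics of similar strategies in fluctuating
environments: simulation, invasion-fitness estimation, local second-order
expansion of the fitness landscape, and classification of invasion
outcomes (substitution, protected coexistence, mutual exclusion).

The package targets structured and unstructured population models of the
form

```
dn_i/dt = f(x_i, e, θ) n_i                      (per-capita growth)
de1/dt  = G1(e, θ) + Σ_j H1(x_j, e, θ) n_j      (environment ODE)
e2      = G2(e, θ) + Σ_j H2(x_j, e, θ) n_j      (implicit environment)
dθ      = A(θ) dt + B(θ) dW                     (external driver, Itô)
```

where `x_i` are strategy vectors, `e = (e1, e2)` is the environmental
feedback, and `θ` is an autonomous stochastic driver (for example an
Ornstein–Uhlenbeck process) unaffected by the populations. Structured
models replace the scalar growth rate by an `ℓ×ℓ` transition-rate matrix
acting on per-strategy class-abundance vectors.

## Quick start

```python
import numpy as np
import fluctinvade as fi

spec = fi.make_example_model("chemostat")
x = np.array([2.0, 0.8, 0.095])   # resident (uptake, yield, death)
y = np.array([1.99, 0.85, 0.09])  # mutant

# invasion fitness: closed form and simulation-based estimate
print(fi.invasion_fitness(spec, x, y, method="closed_form").value)
cfg = fi.SimulationConfig(dt=0.01, t_end=2000.0, seed=0, record_stride=10)
print(fi.invasion_fitness(spec, x, y, method="ergodic", config=cfg))

# selection gradient and second-order coefficient matrices
exp = fi.second_order_coefficients(spec, x, method="closed_form")
print(exp.gradient, exp.conservation_defect)

# classify the outcome of a similar-pair invasion
s12, s21 = fi.expand_fitness_second_order(exp, np.zeros(3),
                                          np.array([-1.0, 5.0, -0.5]), 0.01)
stats = fi.compute_regime_stats(exp, np.zeros(3), np.array([-1.0, 5.0, -0.5]))
print(fi.classify_outcome(s12, s21, stats).outcome)
```

## Built-in example models

| fixture          | description                                               |
|------------------|-----------------------------------------------------------|
| `chemostat`      | resource competition with a fluctuating inflow (OU driver)|
| `lotka_volterra` | competition kernel on a trait axis, fluctuating r and K   |
| `sirs`           | structured SIRS epidemic, fluctuating transmission        |
| `prey_predator`  | deterministic prey timidity model with a limit cycle      |
| `analytic`       | user-supplied two-argument fitness, for testing           |

## Command line

```
fluctinvade simulate  --fixture chemostat --x 2,0.8,0.095 --t-end 100 --out run/
fluctinvade diagnose  --fixture chemostat --x 2,0.8,0.095
fluctinvade fitness   --fixture chemostat --x 2,0.8,0.095 --y 1.99,0.85,0.09 --method closed_form
fluctinvade expansion --fixture analytic --x 0.3
fluctinvade classify  --s12 0.02 --s21 0.01 --quad 1.0
fluctinvade slowfast  --fixture chemostat --x 2,0.8,0.095 --xi2 -1,5,-0.5 --eps 0.05
fluctinvade pip       --fixture analytic --range -1,1 --n 21
fluctinvade demo      chemostat
```

Each command writes its artifacts plus a `manifest.json` (fixture,
overrides, seed, package version) into `--out`; runs with the same seed are
byte-identical. Invalid arguments exit with code 2, numerical failures with
code 1.

## Layout

- `src/fluctinvade/model_core.py` — model/driver specifications, validation
- `src/fluctinvade/simulate.py` — Euler–Maruyama simulation, trajectories
- `src/fluctinvade/resident_analysis.py` — ergodic averages, resident
  diagnostics, period detection, Hopf location
- `src/fluctinvade/invasion.py` — invasion fitness (closed-form / ergodic /
  periodic / equilibrium), gradients, C matrices, singular strategies
- `src/fluctinvade/classification.py` — averaged slow frequency dynamics and
  outcome classification
- `src/fluctinvade/dimorphic.py` — dimorphic (size, frequency) simulation
  and slow–fast validation
- `src/fluctinvade/pip_mip.py` — pairwise/mutual invasibility grids
- `src/fluctinvade/examples.py` — the fixtures above
- `docs/methods.md` — numerical methods and conventions

## Tests

```
python -m pytest
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance suite compares against published reference values; a few
reference values are known not to reproduce under a literal reading of
their source formulas and the corresponding tests fail honestly at the
published tolerance (see `docs/methods.md`).
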