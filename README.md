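# dnadapt

Phenotype-structured population dynamics of **adaptation to DNA damage**: a
simulator and analysis toolkit for a cooperative two-population non-local PDE
model of how natural selection shapes when — and how reproducibly — cells
override the DNA-damage checkpoint.

## The model

Eukaryotic cells facing DNA damage first attempt repair and, if repair fails
for too long, *adapt*: they override the checkpoint and resume division with
the damage still present. Two heritable traits characterise the phenomenon:
the mean adaptation timing `x` (in cell cycles) and the heterogeneity `p`
(the steepness of the logistic adaptation-rate curve; large `p` means nearly
deterministic timing). The package models a population of healthy cells
`n(x,t)` and adapted cells `a(x,t)` structured by one of these traits:

```
eps dn/dt = eps^2 d1 Lap n + n (r1(x) - N(t)) + delta1 a
eps da/dt = eps^2 d2 Lap a + a (r2    - N(t)) + delta2(x) n
N(t) = integral of (n + a)
```

with homogeneous Neumann boundaries. Mutations act as trait diffusion
(`d1`, `d2`), all cells compete through the total mass `N(t)`, and `eps`
scales the system into the rare-mutation / long-time regime. The
coefficients are not free: they are built from biological rates via the
quasi-static treatment of the damaged compartment. A damaged cell repairs at
a Gaussian-in-time rate `alpha(s) = alpha_m exp(-(s-mu_a)^2 / (2 sigma))`,
adapts at a logistic rate `beta(x,s) = beta_m / (1 + exp(-p(s-x)))`, or dies
at rate `gamma_d`; integrating the survival kernel
`K(x,s) = exp(-gamma_d s - int alpha - int beta)` splits these fates into
probabilities that sum to one and yields `r1(x)`, `delta2(x)`.

The central analysis object is the **Hamiltonian fitness**

```
r_H(x) = ( r1 + r2 + sqrt((r1 - r2)^2 + 4 delta1 delta2) ) / 2,
```

the principal-eigenvalue growth rate of the cooperating pair: as `eps -> 0`
the population concentrates as a Dirac mass at `argmax r_H` — the selected
trait. Supporting theory implemented and checked numerically: the ratio
`n/a` relaxes to the root `q(x)` of a trait-dependent quadratic, the total
mass stays in a computable band `[c_N, C_N]`, and the stationary profile is
the ground state of `-eps^2 Lap - r_inf` with `r_inf = r_H`.

Default biological rates: `gamma_d = 0.1`, `gamma_a = 0.35`,
`alpha_m = beta_m = 0.5`, `sigma = 0.5`, `mu_a = 1`, plus the configurable
repair rate of adapted cells `delta = 0.05` and damage rate `D = 0.3`.

## Worked example

```python
from dnadapt import (BioParams, TraitGrid, argmax_fitness, SolverConfig,
                     default_initial, effective_coefficients,
                     fitness_profile, simulate)

bio = BioParams.timing(p_bar=3.0)        # trait = adaptation timing x
grid = TraitGrid.default()               # [0, 12], h = 0.01
field = effective_coefficients(grid, bio)
x_star = argmax_fitness(fitness_profile(grid, field)).trait
print(f"predicted selected trait x* = {x_star:.3f}")

for eps in (0.05, 0.01, 0.001):
    cfg = SolverConfig(epsilon=eps, t_end=30.0, grid=grid, thin=500)
    traj = simulate(cfg, field, default_initial(grid))
    print(f"eps={eps}: terminal peak {traj.peak[-1]:.3f}, "
          f"spread {traj.spread[-1]:.3f}")
```

prints

```
predicted selected trait x* = 2.628
eps=0.05: terminal peak 3.885, spread 1.519
eps=0.01: terminal peak 3.677, spread 0.735
eps=0.001: terminal peak 2.902, spread 0.193
```

Starting from a Gaussian centred at `x = 5`, the trait distribution narrows
and its peak migrates towards the predicted optimum as mutations become
rarer: at `eps = 0.001` the population has concentrated within 0.3 cell
cycles of `x* = 2.63`. That is the model's core claim — a well-defined
adaptation timing favoured by natural selection.

The `examples/` directory holds one short script per capability
(coefficients and hypothesis checks, fitness landscapes, ratio convergence,
Dirac concentration, stationary ground state, stable-vs-periodic
environment). A thin CLI wraps the same functions:

```
dnadapt fitness --config examples/config.yaml --out profile.csv
dnadapt check   --config examples/config.yaml
```

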