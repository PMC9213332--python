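"""Concentration of the trait distribution as mutations become rare.

Shrinking the scaling parameter eps narrows the population profile and
drives its peak towards the maximiser of the Hamiltonian fitness - the
numerical signature of Dirac-mass concentration at the selected trait.
"""

from dnadapt import (BioParams, DiffusionPair, SolverConfig, TraitGrid,
                     argmax_fitness, default_initial, effective_coefficients,
                     fitness_profile, simulate)

bio = BioParams.timing(p_bar=3.0)
grid = TraitGrid.default()            # h = 0.01 resolves the eps=0.001 peak
field = effective_coefficients(grid, bio)
x_star = argmax_fitness(fitness_profile(grid, field)).trait
print(f"predicted selected trait x* = {x_star:.3f}")

init = default_initial(grid)          # Gaussian centred at x = 5
for eps in (0.05, 0.01, 0.001):
    cfg = SolverConfig(epsilon=eps, t_end=30.0, grid=grid, thin=500)
    traj = simulate(cfg, field, init)
    print(f"eps={eps:<6}: terminal peak {traj.peak[-1]:.3f}, "
          f"spread {traj.spread[-1]:.3f}, |peak - x*| = "
          f"{abs(traj.peak[-1] - x_star):.3f}")

# Spread decreases with eps and the eps=0.001 peak has travelled from the
# initial centre (5.0) to within a fraction of a trait unit of x*.
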