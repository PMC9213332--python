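# Run configuration: a timing-trait study at eps = 0.05.
#
# bio: biological rates, per cell-cycle unless noted.
#   gamma_d      death rate of damaged cells
#   gamma_a      death rate of adapted cells (< 1)
#   delta        repair rate of adapted cells
#   damage_rate  dimensionless damage fraction D in (0, 1)
#   alpha_m / beta_m  maximal repair / adaptation rates
#   sigma        Gaussian repair spread (enters as (s - mu_a)^2 / (2 sigma))
#   mu_a         repair-rate peak time
#   fixed_trait  the non-varying trait (p-bar here)
#   trait_mode   timing_x | heterogeneity_p
bio:
  gamma_d: 0.1
  gamma_a: 0.35
  delta: 0.05
  damage_rate: 0.3
  alpha_m: 0.5
  beta_m: 0.5
  sigma: 0.5
  mu_a: 1.0
  fixed_trait: 3.0
  trait_mode: timing_x

# environment: repair-rate modulation alpha-bar(t), absolute rate scale.
environment:
  mode: constant          # constant | cosine_power
  level: 0.5              # <= alpha_m
  # period: 5.0           # cosine_power only (time units)
  # exponent: 8           # cosine_power only (even integer)

# solver: epsilon is the rare-mutation scale; dt defaults to epsilon.
solver:
  epsilon: 0.05
  t_end: 1.0
  coefficient_mode: static   # static | time_varying_r1
  grid:
    x_max: 12.0             # trait-domain length
    M: 241                  # number of nodes
  diffusion:
    d1: 1.0                 # mutation diffusivity, healthy cells
    d2: 1.0                 # mutation diffusivity, adapted cells
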