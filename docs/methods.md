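# Methods

## Model and scope

`dnadapt` implements a cooperative two-population non-local reaction–
diffusion system for the evolutionary dynamics of adaptation to DNA damage.
Healthy cells `n(x,t)` and adapted cells `a(x,t)` are structured by a single
heritable trait — either the mean adaptation timing `x` or the adaptation
heterogeneity `p` — on a truncated half-line `[0, x_max]` with homogeneous
Neumann boundaries:

    eps dn/dt = eps^2 d1 Lap n + n (r1(x) - N(t)) + delta1 a,
    eps da/dt = eps^2 d2 Lap a + a (r2    - N(t)) + delta2(x) n,
    N(t) = int (n + a) dx.

`eps` jointly accelerates time and rarefies mutations; the regime of
interest is `eps` between 0.05 and 0.0001. The damaged compartment is not
evolved as a PDE: it is treated quasi-statically, i.e. assumed to
equilibrate instantaneously relative to the slow timescale, so each freshly
damaged cell is immediately split between repair (back to `n`), adaptation
(into `a`) and death. The package provides the closed-form quasi-static
damaged density `d(x,s,t) = D n(x,t) K(x,s)` but deliberately does not
solve the age-structured damaged-cell equation.

## Biological rates and effective coefficients

Rates, with time in cell-cycle units:

* repair: `alpha(s,t) = alphabar(t) exp(-(s - mu_a)^2 / (2 sigma))`, with
  `s` the time since damage; defaults `alpha_m = 0.5`, `mu_a = 1`,
  `sigma = 0.5`. The exponent uses `2 sigma` verbatim (not `2 sigma^2`).
* adaptation: `beta(x,s) = beta_m / (1 + exp(-p (s - x)))`, `beta_m = 0.5`.
  In timing mode the grid trait is `x` and `p` is fixed (default 3); in
  heterogeneity mode the grid trait is `p` and `x` is fixed (default 4), and
  the trait enters the kernel only through `beta` (`alpha` is
  trait-independent).
* deaths: `gamma_d = 0.1` (damaged), `gamma_a = 0.35` (adapted); healthy
  cells are the reference with death rate 0.
* `delta = 0.05` (repair rate of adapted cells) and the damage fraction
  `D = 0.3` are not pinned by any published value; they are configurable,
  with `D < 1` and `gamma_a < 1` required.

The survival kernel of a damaged cell,
`K(x,s) = exp(-gamma_d s - int_0^s alpha - int_0^s beta)`, is evaluated
**exactly**: both cumulative integrals have closed forms (error function for
the Gaussian, `softplus/p` for the logistic, with the `p -> 0` limit
`beta_m s / 2` handled explicitly). Only the outer fate integrals

    P_repair = int alpha K ds,  P_adapt = int beta K ds,
    P_death  = gamma_d int K ds

are numerical: composite Simpson on a uniform `s`-grid (step 0.01 by
default) truncated at `s_max = -ln(tail_tol)/gamma_d` (about 276 for the
default `tail_tol = 1e-12`), valid because every integrand is dominated by
`exp(-gamma_d s)`. Probability conservation
`P_repair + P_adapt + P_death = 1` is exact in the model and holds to about
`2e-10` at the default quadrature step; it is the primary correctness check
for this module, and a user-supplied `s_max` that breaks the tail bound is
rejected with the required value named. The effective coefficients are

    r1(x) = 1 - D + D P_repair(x),   r2 = 1 - gamma_a - delta,
    delta1 = delta,                  delta2(x) = D P_adapt(x).

The validator computes the carrying-capacity bracket numerically,
`c_N = min_x min(r1 + delta2, r2 + delta1)` and `C_N = max_x max(...)`, and
reports the closed-form bracket `min(1 - gamma_a, 1 - D)`, `2 + D`
alongside (the numeric values are the ones used downstream). Any node with
`delta_i <= 0` is a hard failure: positivity of the exchange terms is what
makes the system cooperative.

## Spectral fitness analysis

With `R(x,N)` the growth/exchange matrix and `D = diag(d1, d2)`, the
rare-mutation limit is governed by the principal eigenvalue of
`rho^2 D + R`, where `rho` stands for the gradient of the phase
`u = eps log n`. The module computes, in closed form:

* `q_i`, the positive root of `delta_i + b X - delta_j X^2` with
  `b = (d_i - d_j) rho^2 + r_i - r_j`: the asymptotic ratio `n_i / n_j`.
  The root is evaluated in a cancellation-safe form (conjugate expression
  when `b < 0`) so it stays positive and accurate when
  `delta_1 delta_2 << b^2`.
* the Hamiltonian fitness
  `r_H = (r1 + r2 + sqrt(b^2 + 4 delta1 delta2)) / 2` and the effective
  Hamiltonian `H = (d1 + d2)/2 rho^2 + r_H - N`.
* the principal eigenvector, normalised to first component 1. Its second
  component is `q_2 = 1/q_1`: the eigenvector carries the *composition*
  `(n1, n2) ~ (1, n2/n1)`, the reciprocal of the ratio `n1/n2`. (A common
  slip is to place `q_1` there; the eigen-residual test against a dense 2x2
  eigensolver pins the correct choice.)
* the stationary effective fitness
  `r_inf = q/(1+q) (r1 + delta2) + 1/(1+q) (r2 + delta1)`, which equals
  `r_H` nodewise (to machine precision) whenever the diffusion contribution
  drops out.

Exchange identities: `r_j + delta_j q_i = r_H` holds exactly when
`d_1 = d_2` or `rho = 0`; in general the exact statement carries the
diffusion shift, `r_j + d_j rho^2 + delta_j q_i = H + N`. The test suite
asserts the plain form in its regime of validity and the shifted form
everywhere.

For landscape-level work (`fitness_profile`) `rho` defaults to 0: the
studies of record use equal diffusions, where `r_H` is `rho`-independent.
For `d1 != d2` the profile at user-supplied `rho` is exact pointwise but is
not a self-consistent fitness landscape, because the physical `rho` is the
evolving phase gradient of the solution; the package evaluates, it does not
iterate.

The selected trait is `argmax r_H`, located at the discrete maximum and
refined by a 3-point quadratic fit; ties break to the smallest trait, and
boundary maxima and flat profiles are flagged rather than refined (an
increasing heterogeneity-fitness legitimately peaks at the right edge).

## Time integration

Crank–Nicolson for the diffusion, fully explicit for the stiff `1/eps`
reaction and the non-local competition `N`, which is evaluated from the
beginning-of-step state:

    (I - c_i L) v^{k+1} = (I + c_i L) v^k + (dt/eps) [reaction at t_k],
    c_i = eps d_i dt / 2.

`L` is the second-difference operator with mirror-ghost Neumann closure at
both ends; with trapezoid weights it is self-adjoint and mass-conserving
(discrete integration by parts), which makes the logistic law for the total
mass exact at the discrete level when the coefficients are flat. The
implicit solves are banded (tridiagonal) with a dense-inverse fast path for
very small grids. The scheme is first-order in time overall (the explicit
reaction dominates) and second-order on the diffusion-only subproblem; both
orders are verified by self-convergence tests.

Defaults: domain `[0, 12]` with `h = 0.01` (1201 nodes) — several nodes per
peak width down to `eps = 0.001`, since the concentrated profile has width
of order `sqrt(eps)`; `dt = eps` (the explicit reaction is robust for `dt`
of that order), with runs refused when `dt` exceeds a configurable multiple
(default 4) of `eps`. A run records the total mass, the interpolated peak,
the mass-weighted spread, the sup-distance of `n/a` to `q`, and the mass
fraction in the terminal 5% of the domain (a decay monitor that warns when
the Neumann truncation of the half-line stops being harmless; enlarging
`x_max` from 12 to 16 changes the default runs by less than `1e-8`).

The time-varying-environment mode implements the numerically tractable
variant: the kernel exponent stays time-independent and the environmental
modulation `alphabar(t)/alpha_m` multiplies only the repair inflow part of
`r1`, rebuilt each step from the cached repair probability. `alphabar` is
kept on the absolute rate scale (`level <= alpha_m`); the periodic choice is
`alphabar(t) = alpha_m cos(pi t / 5)^8`, so the modulation factor is
`cos(pi t/5)^8` with mean 35/128.

## Stationary analysis

Once `n/a` has relaxed to `q`, the summed density solves
`-eps^2 w'' = w (r_inf - N)` with `N` simultaneously the principal
eigenvalue and the integral of `w` — the normalisation `int w = N_inf`
implements that closure. The discrete operator `eps^2 L + diag(r_inf)` is
symmetrised by the trapezoid-weight similarity transform and solved with a
dense symmetric-tridiagonal eigensolver (grids of a few thousand nodes make
iterative methods unnecessary); the principal eigenvector is strictly
positive (Perron structure), the sign is fixed on the largest entry, and
the unweighted residual is checked against `1e-8 * max|w|`.

Numerical subtlety worth recording: for an exactly quadratic fitness
`r = r0 - k (x - x0)^2` with interior `x0`, the continuum eigenvalue is
`r0 - eps sqrt(k)` with only exponentially small domain corrections, so at
fixed `h` the measured deviation is pure `O(h^2)` discretisation error and
does not shrink with `eps`. Convergence studies therefore scale the
resolution with the profile width (`h ~ eps`, a few nodes per
`sqrt(eps)`-wide peak), under which the total deviation scales as `eps^2`.
When `x0` approaches 0 the Neumann image distorts the harmonic closed form;
tests keep `x0` well interior.

## Diagnostics

* Hopf–Cole fields `u = eps log(max(density, 1e-300))`; the floor only
  guards the logarithm, and "active region" for band checks means density
  above `1e-30` of the peak.
* `ratio_distance`: `sup |n/a - q|` over a window (default `[0, 10]`),
  restricted to nodes where the adapted density is within 8 decades of its
  peak (`rel_floor = 1e-8`). The restriction is deliberate: towards the
  vacuum fringe the finite-`eps` correction to the ratio grows with the
  squared log-density gradient (a transport effect of order
  `eps (d_x log a)^2 x` width), so a fringe-inclusive supremum measures
  phase noise in regions carrying no population. Within the active region
  the distance falls below `1e-2` by `t = 1` at `eps = 0.01` and decays
  monotonically up to `O(1e-4)` node-switching wiggles of the discrete
  supremum.
* `ratio_band_check` reports the excess of `u1 - u2` outside the asymptotic
  band `eps [ln q +/- eps^4 / t]`; the bound is asymptotic in `eps`, so the
  report records rather than asserts.
* `concentration`: interpolated peak (leftmost on ties), trapezoid-weighted
  mean and spread, and the right-tail mass fraction.
* `mass_bounds_check`: compares recorded `N(t)` with
  `[c_N - tol, C_N + tol]` (default `tol = 0.05`). The uniform bound is
  guaranteed only for initial masses already inside `[c_N, C_N]`; the
  standard small Gaussian datum starts at `N(0) ~ 0.22 < c_N = 0.65`, so
  the check applies from the first recorded entry into the band (which the
  `1/eps` logistic growth reaches within a fraction of a time unit).

## Preset studies and chosen horizons

Presets bundle the canonical runs: ratio convergence (`eps = 0.01`,
horizon 1), Dirac concentration across
`eps in {0.05, 0.01, 0.001, 0.0001}`, diffusion-asymmetry robustness
(`(d1,d2) in {(1,1),(0.5,1.5),(0.05,1.95),(0,2)}`, `eps = 0.001`), the
heterogeneity trait in a stable environment, and the stable-vs-periodic
contrast (horizon 300 by default). Horizons for the concentration and
asymmetry studies are this package's choice: `t_end = 30`, selected so that
the `eps = 0.001` peak, travelling from the initial centre at 5, reaches
the fitness maximum (`x* = 2.63` at default rates; it arrives within 0.5
trait units around `t = 25`). Scaled-down variants (shorter horizons,
coarser grids) are used in tests and are flagged as such by their configs.
The pipeline is seed-free and byte-deterministic: identical configs
reproduce identical output files, which the suite manifest checksums.

## Known limitations

* The heterogeneity-mode landscape at the default rates peaks at a small
  interior `p` (about 2.2 for `x = 4`) and is then very slightly decreasing:
  `r1(p)` saturates once adaptation no longer overlaps the Gaussian repair
  window, while `delta2(p)` keeps falling. Whether `r_H(p)` increases out
  to large `p` is controlled entirely by the unconstrained rate `delta`
  (it would require `delta < ~2e-4`, independently of `D`); with the
  default `delta = 0.05` a population started at `p = 5` in a stable
  environment drifts slowly left, not right, while the periodically hostile
  environment still produces the much stronger leftward (bet-hedging)
  displacement. The environment-contrast test asserts the stronger
  stable-rightward behaviour and documents this failure rather than hiding
  it.
* The explicit treatment of the `1/eps` reaction caps the overall temporal
  order at one; an asymptotic-preserving discretisation is out of scope.
* For `d1 != d2` the package evaluates fitness at user-supplied phase
  gradients only; no self-consistent landscape is claimed in that regime.
* The quasi-static damaged compartment removes damaged cells from the
  competition mass; the full age-structured system is not solved, so any
  feature depending on the damaged compartment's transient is outside what
  these simulations can show.
* Everything here is synthetic-model verification: passing tests show the
  solver and analysis reproduce the model's mathematics, not that the model
  fits any particular experimental dataset.
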