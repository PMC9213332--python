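"""Quantitative checks of the asymptotic predictions on simulation output.

The rare-mutation theory makes three falsifiable claims about finite-eps
runs: the total mass stays in a computable band [c_N, C_N]; the ratio of the
two densities relaxes to the trait-dependent root q(x) (equivalently, the
phase difference u1 - u2 sits in a band of width eps^5/t around eps*ln q);
and the densities concentrate (shrinking spread) around the maximiser of the
Hamiltonian fitness as eps decreases.  This module operationalises each claim
as a measurement on states and trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .fitness import FitnessProfile, _quadratic_peak
from .solver import PopulationState, TraitGrid, Trajectory
from .rates import AssumptionReport

__all__ = [
    "HopfColeField",
    "ConcentrationSummary",
    "RatioBandReport",
    "MassBoundsReport",
    "hopf_cole",
    "ratio_distance",
    "ratio_band_check",
    "concentration",
    "mass_bounds_check",
]

LOG_FLOOR = 1e-300          # densities below this are numerical zero
ACTIVE_REL = 1e-30          # active region: density > ACTIVE_REL * max


@dataclass(frozen=True)
class HopfColeField:
    """Phase field u = eps * log(density), floored for vanishing densities."""

    u: NDArray
    epsilon: float
    floor: float = LOG_FLOOR

    def density(self) -> NDArray:
        """Inverse transform exp(u / eps)."""
        return np.exp(self.u / self.epsilon)


def hopf_cole(density: ArrayLike, epsilon: float,
              floor: float = LOG_FLOOR) -> HopfColeField:
    """Hopf-Cole transform u = eps * log(max(density, floor))."""
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    return HopfColeField(u=epsilon * np.log(np.maximum(density, floor)),
                         epsilon=epsilon, floor=floor)


RATIO_REL_FLOOR = 1e-8      # ratio is measured where the population lives


def ratio_distance(state: PopulationState, profile: FitnessProfile,
                   window: tuple[float, float] = (0.0, 10.0),
                   rel_floor: float = RATIO_REL_FLOOR) -> float:
    """sup over the window of |n/a - q|.

    The supremum is taken where the adapted population is numerically
    present (a > rel_floor * max a, default within 8 decades of the peak):
    towards the vacuum fringe the finite-eps correction to the ratio grows
    with the squared log-density gradient, so a fringe-inclusive supremum
    measures phase noise where the populations are absent.  Excluded
    sub-regions simply drop out; an entirely excluded window reports nan.
    """
    lo, hi = window
    mask = (profile.nodes >= lo) & (profile.nodes <= hi)
    a = state.a[mask]
    n = state.n[mask]
    q = profile.q[mask]
    active = a > rel_floor * max(float(state.a.max()), LOG_FLOOR)
    if not np.any(active):
        return float("nan")
    return float(np.max(np.abs(n[active] / a[active] - q[active])))


@dataclass(frozen=True)
class RatioBandReport:
    """Excess of u1 - u2 outside the band eps*(ln q +/- eps^4/t)."""

    max_excess: float
    band_halfwidth: float
    active_nodes: int
    t: float


def ratio_band_check(u1: HopfColeField, u2: HopfColeField,
                     profile: FitnessProfile, epsilon: float,
                     t: float) -> RatioBandReport:
    """Measure how far the phase difference strays from eps*ln q.

    The theoretical band eps*[ln q - eps^4/t, ln q + eps^4/t] holds
    asymptotically; the report records the worst excess over the active
    region rather than asserting zero.
    """
    if t <= 0:
        raise ValueError("the ratio band is defined for positive times")
    diff = u1.u - u2.u
    centre = epsilon * np.log(profile.q)
    half = epsilon * epsilon ** 4 / t
    dens = np.exp(u1.u / epsilon) + np.exp(u2.u / epsilon)
    active = dens > ACTIVE_REL * max(float(dens.max()), LOG_FLOOR)
    excess = np.abs(diff[active] - centre[active]) - half
    return RatioBandReport(max_excess=float(np.max(excess, initial=0.0)),
                           band_halfwidth=float(half),
                           active_nodes=int(active.sum()), t=t)


@dataclass(frozen=True)
class ConcentrationSummary:
    """Peak location, mass-weighted mean/spread and right-tail mass share."""

    peak: float
    mean: float
    spread: float
    mass_tail: float


def concentration(state: PopulationState | ArrayLike,
                  grid: TraitGrid) -> ConcentrationSummary:
    """Concentration metrics of the summed density.

    The peak is the discrete maximum refined by a 3-point quadratic fit
    (leftmost node on ties); mean and spread are trapezoid-weighted moments
    of the normalised density; mass_tail is the mass fraction in the last 5%
    of the domain.
    """
    dens = state.total if isinstance(state, PopulationState) \
        else np.asarray(state, dtype=float)
    w = grid.weights
    x = grid.nodes
    mass = float(w @ dens)
    if mass <= 0:
        raise ValueError("concentration needs positive total mass")
    i = int(np.argmax(dens))
    peak = float(x[i]) if i in (0, len(x) - 1) else _quadratic_peak(x, dens, i)
    pdf = dens / mass
    mean = float(w @ (x * pdf))
    var = float(w @ ((x - mean) ** 2 * pdf))
    tail_start = int(0.95 * (grid.M - 1))
    mass_tail = float(w[tail_start:] @ dens[tail_start:]) / mass
    return ConcentrationSummary(peak=peak, mean=mean,
                                spread=float(np.sqrt(max(var, 0.0))),
                                mass_tail=mass_tail)


@dataclass(frozen=True)
class MassBoundsReport:
    """Comparison of the recorded total mass with the band [c_N, C_N].

    The uniform bound is guaranteed only when the initial mass already lies
    in the band; when it does not (the standard small Gaussian initial datum
    has N(0) ~ 0.22 < c_N), the check applies from the first recorded time
    the mass enters the band.
    """

    c_N: float
    C_N: float
    entry_time: float | None
    worst_excess: float
    worst_time: float | None
    n_violations: int
    tol: float

    @property
    def ok(self) -> bool:
        return self.entry_time is not None and self.n_violations == 0


def mass_bounds_check(trajectory: Trajectory,
                      report: AssumptionReport | None = None,
                      tol: float = 0.05) -> MassBoundsReport:
    """Flag recorded masses outside [c_N - tol, C_N + tol] after the mass
    first enters the band; return the worst excursion and its time."""
    if report is not None:
        c_N, C_N = report.c_N, report.C_N
    elif trajectory.c_N is not None:
        c_N, C_N = trajectory.c_N, trajectory.C_N
    else:
        raise ValueError("no assumption constants available")
    N = trajectory.N
    t = trajectory.times
    inside = (N >= c_N) & (N <= C_N)
    if not np.any(inside):
        return MassBoundsReport(c_N=c_N, C_N=C_N, entry_time=None,
                                worst_excess=float("inf"), worst_time=None,
                                n_violations=len(N), tol=tol)
    k0 = int(np.argmax(inside))
    seg_N, seg_t = N[k0:], t[k0:]
    excess = np.maximum(seg_N - (C_N + tol), (c_N - tol) - seg_N)
    worst = int(np.argmax(excess))
    n_viol = int(np.sum(excess > 0))
    return MassBoundsReport(
        c_N=c_N, C_N=C_N, entry_time=float(t[k0]),
        worst_excess=float(excess[worst]),
        worst_time=float(seg_t[worst]) if n_viol else None,
        n_violations=n_viol, tol=tol)
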