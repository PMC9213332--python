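"""Spectral analysis of the coupled growth matrix.

The two-population system couples growth matrix
R(x, N) = [[r1 - N, delta1], [delta2, r2 - N]] with diffusion
D = diag(d1, d2).  In the rare-mutation (Hamilton-Jacobi) limit the dynamics
of the phase u = eps*log(n) is governed by the principal eigenvalue of
rho^2 D + R, where rho stands for the phase gradient.  This module provides:

* ``q_root`` -- the asymptotic population ratio n_i/n_j, positive root of the
  trait-dependent quadratic  delta_i + b X - delta_j X^2  with
  b = (d_i - d_j) rho^2 + r_i - r_j;
* ``hamiltonian_fitness`` -- r_H, the effective growth rate of the cooperating
  pair (the principal-eigenvalue contribution net of diffusion and
  competition);
* ``hamiltonian`` -- the full effective Hamiltonian
  (d1+d2)/2 rho^2 + r_H - N;
* ``principal_eigenvector`` -- the strictly positive eigenvector (1, q1);
* ``effective_fitness_r_inf`` -- the ratio-weighted stationary fitness, which
  coincides with r_H when d1 = d2;
* ``argmax_fitness`` -- the trait selected in the limit (peak of r_H, refined
  by quadratic interpolation).

All operations are vectorised over trait nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .rates import CoefficientField

__all__ = [
    "DiffusionPair",
    "FitnessProfile",
    "SpectralPoint",
    "ArgmaxResult",
    "q_root",
    "hamiltonian_fitness",
    "hamiltonian",
    "principal_eigenvector",
    "effective_fitness_r_inf",
    "fitness_profile",
    "argmax_fitness",
]


@dataclass(frozen=True)
class DiffusionPair:
    """Mutation (diffusion) coefficients of the two populations.

    Both must be non-negative and at least one positive: a population with no
    mutational input of its own still inherits trait diversity through the
    exchange with the other one, but two frozen populations cannot spread.
    """

    d1: float = 1.0
    d2: float = 1.0

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if self.d1 == 0 and self.d2 == 0:
            raise ValueError("(d1, d2) = (0, 0) is not allowed")

    @property
    def symmetric(self) -> bool:
        return self.d1 == self.d2


def _coeffs_at(field: CoefficientField, x: ArrayLike):
    x = np.asarray(x, dtype=float)
    if x.shape == field.nodes.shape and np.array_equal(x, field.nodes):
        return field.r1, field.r2, field.delta1, field.delta2
    return field.at(x)


def _positive_root(b: NDArray, di: NDArray, dj: NDArray) -> NDArray:
    """Positive root of dj X^2 - b X - di = 0, cancellation-safe.

    Uses (b + s)/(2 dj) when b >= 0 and the conjugate form 2 di / (s - b)
    when b < 0, so the result stays positive and accurate when
    di*dj << b^2.
    """
    s = np.hypot(b, 2.0 * np.sqrt(di * dj))
    return np.where(b >= 0, (b + s) / (2.0 * dj), 2.0 * di / (s - b))


def q_root(x: ArrayLike, rho: float, diff: DiffusionPair,
           field: CoefficientField, which: int = 1) -> NDArray | float:
    """Asymptotic ratio q_i = n_i / n_j at trait ``x`` and phase gradient
    ``rho``.

    ``which`` selects i in {1, 2} (j is the other index).  Requires
    delta_j > 0.
    """
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    r1, r2, e1, e2 = _coeffs_at(field, x)
    if which == 1:
        di, dj = e1, e2
        b = (diff.d1 - diff.d2) * rho ** 2 + (r1 - r2)
    else:
        di, dj = e2, e1
        b = (diff.d2 - diff.d1) * rho ** 2 + (r2 - r1)
    if np.any(np.asarray(dj) <= 0):
        raise ValueError("q_i requires delta_j > 0")
    q = _positive_root(np.asarray(b, dtype=float),
                       np.asarray(di, dtype=float), np.asarray(dj, dtype=float))
    return q if q.ndim else float(q)


def hamiltonian_fitness(x: ArrayLike, rho: float, diff: DiffusionPair,
                        field: CoefficientField) -> NDArray | float:
    """Hamiltonian fitness r_H = (r1 + r2 + sqrt(b^2 + 4 delta1 delta2))/2
    with b = (d1 - d2) rho^2 + (r1 - r2).

    Independent of ``rho`` when d1 = d2.
    """
    r1, r2, e1, e2 = _coeffs_at(field, x)
    b = (diff.d1 - diff.d2) * rho ** 2 + (r1 - r2)
    out = 0.5 * (r1 + r2 + np.hypot(b, 2.0 * np.sqrt(e1 * e2)))
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def hamiltonian(rho: float, N: float, x: ArrayLike, diff: DiffusionPair,
                field: CoefficientField) -> NDArray | float:
    """Effective Hamiltonian H(rho, N) = (d1+d2)/2 rho^2 + r_H(x, rho) - N,
    the principal eigenvalue of rho^2 D + R(x, N)."""
    rh = hamiltonian_fitness(x, rho, diff, field)
    return 0.5 * (diff.d1 + diff.d2) * rho ** 2 + rh - N


@dataclass(frozen=True)
class SpectralPoint:
    """Principal eigenpair of rho^2 D + R(x, N) at one trait point."""

    eigenvalue: float
    psi: tuple[float, float]
    x: float
    rho: float
    N: float
    residual: float


def principal_eigenvector(x: float, rho: float, diff: DiffusionPair,
                          field: CoefficientField, N: float) -> SpectralPoint:
    """Principal eigenvector of rho^2 D + R(x, N), normalised to first
    component 1; both components strictly positive.

    The second component is q2 = 1/q1: the eigenvector direction carries the
    asymptotic composition (n1, n2) ~ (1, n2/n1), i.e. the reciprocal of the
    ratio q1 = n1/n2.
    """
    r1, r2, e1, e2 = (float(v) for v in _coeffs_at(field, float(x)))
    if e2 <= 0:
        raise ValueError("principal eigenvector requires delta_2 > 0")
    q2 = float(q_root(float(x), rho, diff, field, which=2))
    H = float(hamiltonian(rho, N, float(x), diff, field))
    A = np.array([[diff.d1 * rho ** 2 + r1 - N, e1],
                  [e2, diff.d2 * rho ** 2 + r2 - N]])
    psi = np.array([1.0, q2])
    res = float(np.max(np.abs(A @ psi - H * psi)))
    return SpectralPoint(eigenvalue=H, psi=(1.0, q2), x=float(x), rho=rho,
                         N=N, residual=res)


def effective_fitness_r_inf(grid, field: CoefficientField) -> NDArray:
    """Stationary effective fitness of the summed population,

        r_inf = q/(1+q) (r1 + delta2) + 1/(1+q) (r2 + delta1),

    the growth rate felt by w = n + a once the ratio n/a has relaxed to q.
    Defined in the equal-diffusion regime (q is then rho-independent); equals
    the Hamiltonian fitness nodewise.
    """
    nodes = np.asarray(getattr(grid, "nodes", grid), dtype=float)
    r1, r2, e1, e2 = _coeffs_at(field, nodes)
    q = _positive_root(np.asarray(r1 - r2, dtype=float), e1, e2)
    return q / (1.0 + q) * (r1 + e2) + 1.0 / (1.0 + q) * (r2 + e1)


@dataclass(frozen=True)
class FitnessProfile:
    """q, r_H and r_inf sampled on a trait grid for one diffusion pair."""

    nodes: NDArray
    q: NDArray
    r_H: NDArray
    r_inf: NDArray
    rho_used: float
    diff: DiffusionPair

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"trait": self.nodes, "q": self.q,
                             "r_H": self.r_H, "r_inf": self.r_inf})


def fitness_profile(grid, field: CoefficientField,
                    diff: DiffusionPair = DiffusionPair(1.0, 1.0),
                    rho: float = 0.0) -> FitnessProfile:
    """Sample q, r_H and r_inf on the grid at a fixed phase gradient.

    ``rho`` defaults to 0; for d1 = d2 the profile is rho-independent.
    """
    nodes = np.asarray(getattr(grid, "nodes", grid), dtype=float)
    q = np.asarray(q_root(nodes, rho, diff, field, which=1), dtype=float)
    r_H = np.asarray(hamiltonian_fitness(nodes, rho, diff, field), dtype=float)
    r_inf = effective_fitness_r_inf(nodes, field)
    return FitnessProfile(nodes=nodes, q=q, r_H=r_H, r_inf=r_inf,
                          rho_used=rho, diff=diff)


@dataclass(frozen=True)
class ArgmaxResult:
    """Location of the selected trait (peak of a fitness profile)."""

    trait: float
    index: int
    value: float
    on_boundary: bool
    flat: bool


def _quadratic_peak(x: NDArray, y: NDArray, i: int) -> float:
    """Vertex of the parabola through nodes i-1, i, i+1 (uniform or not)."""
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    if a >= 0:  # not locally concave; keep the node
        return float(x1)
    xv = -b / (2.0 * a)
    return float(np.clip(xv, x0, x2))


def argmax_fitness(profile: FitnessProfile | tuple[NDArray, NDArray],
                   flat_tol: float = 1e-12) -> ArgmaxResult:
    """Trait maximising the Hamiltonian fitness.

    The discrete maximum is refined by a 3-point quadratic fit when interior;
    ties are broken towards the smallest trait.  A boundary maximum and a
    flat profile are flagged rather than treated as errors (an increasing
    heterogeneity-fitness legitimately peaks at the right edge).
    """
    if isinstance(profile, FitnessProfile):
        x, y = profile.nodes, profile.r_H
    else:
        x, y = (np.asarray(v, dtype=float) for v in profile)
    i = int(np.argmax(y))  # np.argmax already takes the first (leftmost) max
    flat = bool(np.ptp(y) <= flat_tol * max(1.0, np.max(np.abs(y))))
    on_boundary = i == 0 or i == len(y) - 1
    trait = float(x[i]) if on_boundary or flat else _quadratic_peak(x, y, i)
    return ArgmaxResult(trait=trait, index=i, value=float(y[i]),
                        on_boundary=on_boundary, flat=flat)
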