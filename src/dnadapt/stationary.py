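"""Stationary analysis: ground state of the effective Schroedinger operator.

Once the ratio n/a has relaxed to q(x), the summed stationary density
w = n + a solves the one-population eigenproblem

    -eps^2 w'' = w (r_inf(x) - N_inf),        w > 0,  int w = N_inf,

i.e. (eps^2 Lap + diag(r_inf)) w = N_inf w with N_inf the principal
eigenvalue: the limit total mass is the ground-state energy of
-eps^2 Lap - r_inf (up to sign), and the profile concentrates around the
maximiser of r_inf as eps -> 0 with width O(sqrt(eps)).

The discrete operator uses the same mirror-ghost Neumann Laplacian as the
time integrator; its trapezoid-weighted symmetrisation is an ordinary
symmetric tridiagonal matrix, so the principal pair comes from a dense
tridiagonal eigensolve (grids of a few thousand nodes make iterative methods
unnecessary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.linalg import eigh_tridiagonal

from .solver import TraitGrid, Trajectory, build_neumann_laplacian

__all__ = ["GroundState", "ground_state", "stationary_consistency",
           "StationaryReport"]


@dataclass(frozen=True)
class GroundState:
    """Principal eigenpair of eps^2 Lap + diag(r): stationary profile and
    limit mass."""

    nodes: NDArray
    w: NDArray
    N_inf: float
    residual: float
    epsilon: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.nodes, "w": self.w})


def ground_state(r_profile: ArrayLike, epsilon: float,
                 grid: TraitGrid, *, residual_tol: float = 1e-8) -> GroundState:
    """Largest-eigenvalue eigenpair of eps^2 Lap_h + diag(r_profile).

    The eigenvector is strictly positive (Perron structure of the tridiagonal
    operator) and scaled so that its trapezoid integral equals the eigenvalue
    N_inf, matching the stationary constraint that the total mass feeds back
    as the competition level.  N_inf <= max r_profile always.
    """
    r = np.asarray(r_profile, dtype=float)
    if r.shape != (grid.M,):
        raise ValueError("r_profile must be sampled on the grid")
    if not np.all(np.isfinite(r)):
        raise ValueError("r_profile must be finite")
    lap = build_neumann_laplacian(grid)
    d_sym, e_sym = lap.symmetrized()
    diag = epsilon ** 2 * d_sym + r
    off = epsilon ** 2 * e_sym
    vals, vecs = eigh_tridiagonal(diag, off, select="i",
                                  select_range=(grid.M - 1, grid.M - 1))
    N_inf = float(vals[0])
    if N_inf <= 0:
        raise ValueError(
            f"principal eigenvalue {N_inf:g} is non-positive: the stationary "
            "population is extinct for this fitness profile")
    # undo the similarity transform W^{1/2} . W^{-1/2}
    sqrt_w = np.sqrt(grid.weights)
    w = vecs[:, 0] / sqrt_w
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    w = w * (N_inf / float(grid.weights @ w))
    residual = float(np.max(np.abs(
        epsilon ** 2 * lap.matvec(w) + (r - N_inf) * w)))
    scale = float(np.max(np.abs(w)))
    if residual > residual_tol * scale:
        raise RuntimeError(
            f"eigen-residual {residual:.3e} exceeds {residual_tol:g} * scale")
    return GroundState(nodes=grid.nodes, w=w, N_inf=N_inf,
                       residual=residual, epsilon=epsilon)


@dataclass(frozen=True)
class StationaryReport:
    """Distance of a late-time simulation from the predicted ground state."""

    l1_distance: float        # ||(n+a)(t_end) - w||_L1 / N_inf
    mass_gap: float           # |N(t_end) - N_inf|
    t_end: float


def stationary_consistency(trajectory: Trajectory,
                           gs: GroundState) -> StationaryReport:
    """Compare the terminal state of a run with the ground-state prediction.

    Both discrepancies are asymptotic (t -> infinity at fixed eps), so this
    reports rather than asserts; along a doubling sequence of horizons they
    should shrink.
    """
    grid = trajectory.config.grid
    if gs.nodes.shape != grid.nodes.shape or gs.nodes[-1] != grid.x_max:
        raise ValueError("trajectory and ground state use different grids")
    dens = trajectory.final_state.total
    l1 = float(grid.weights @ np.abs(dens - gs.w)) / gs.N_inf
    gap = abs(float(trajectory.N[-1]) - gs.N_inf)
    return StationaryReport(l1_distance=l1, mass_gap=gap,
                            t_end=float(trajectory.times[-1]))
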