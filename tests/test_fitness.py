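"""Spectral fitness algebra: the ratio root q, r_H, the Hamiltonian and the
principal eigenpair, against brute-force root finding and a generic 2x2
eigensolver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from dnadapt import (
    CoefficientField, DiffusionPair, argmax_fitness, effective_coefficients,
    effective_fitness_r_inf, fitness_profile, hamiltonian,
    hamiltonian_fitness, principal_eigenvector, q_root,
)
NODES = np.linspace(0.0, 12.0, 5)


def flat(r1, r2, d1, d2):
    return CoefficientField.constant(NODES, r1, r2, d1, d2)


def _sample(rng, n):
    """Randomised admissible inputs (delta_i > 0, d >= 0, not both zero)."""
    r1 = rng.uniform(-1, 2, n)
    r2 = rng.uniform(-1, 2, n)
    e1 = 10.0 ** rng.uniform(-6, 0, n)
    e2 = 10.0 ** rng.uniform(-6, 0, n)
    d1 = rng.uniform(0, 2, n)
    d2 = rng.uniform(0, 2, n)
    d2[d1 + d2 == 0] = 1.0
    rho = rng.uniform(0, 3, n)
    N = rng.uniform(0, 3, n)
    return r1, r2, e1, e2, d1, d2, rho, N


# ----------------------------------------------------------------- q root ----

def test_q_symmetric_cases():
    f = flat(1.0, 1.0, 0.04, 0.25)
    assert q_root(0.0, 0.0, DiffusionPair(1, 1), f) == pytest.approx(
        np.sqrt(0.04 / 0.25))
    f = flat(1.0, 1.0, 0.3, 0.3)
    assert q_root(0.0, 0.7, DiffusionPair(1, 1), f) == pytest.approx(1.0)


def test_q_matches_bisection_oracle():
    rng = np.random.default_rng(7)
    r1, r2, e1, e2, d1, d2, rho, _ = _sample(rng, 200)
    for k in range(200):
        f = flat(r1[k], r2[k], e1[k], e2[k])
        diff = DiffusionPair(d1[k], d2[k])
        q = float(q_root(0.0, rho[k], diff, f, which=1))
        b = (d1[k] - d2[k]) * rho[k] ** 2 + (r1[k] - r2[k])

        def P(X):
            return e1[k] + b * X - e2[k] * X ** 2

        hi = 10.0
        while P(hi) > 0:
            hi *= 10.0
        q_ref = brentq(P, 0.0, hi, xtol=1e-14, rtol=1e-15)
        assert q == pytest.approx(q_ref, abs=1e-10, rel=1e-10)
        assert q > 0


def test_q_cancellation_safe_regime():
    # delta1*delta2 << (r1-r2)^2 with r1 < r2: naive formula would cancel
    f = flat(0.0, 2.0, 1e-12, 1e-12)
    q = float(q_root(0.0, 0.0, DiffusionPair(1, 1), f))
    # q ~ delta1/(r2 - r1) for a strongly disadvantaged population 1
    assert q == pytest.approx(1e-12 / 2.0, rel=1e-6)


def test_q_requires_positive_delta():
    f = flat(1.0, 0.5, 0.1, 0.0)
    with pytest.raises(ValueError):
        q_root(0.0, 0.0, DiffusionPair(1, 1), f, which=1)


# ------------------------------------------------------------ Hamiltonian ----

def test_r_H_rho_independent_when_diffusions_equal():
    f = flat(0.9, 0.6, 0.05, 0.07)
    vals = [hamiltonian_fitness(0.0, rho, DiffusionPair(1.3, 1.3), f)
            for rho in (0.0, 0.5, 2.0)]
    assert np.ptp(vals) == 0.0


def test_r_H_degenerate_exchange_limit():
    f = flat(0.9, 0.6, 1e-15, 1e-15)
    assert hamiltonian_fitness(0.0, 0.0, DiffusionPair(1, 1), f) == \
        pytest.approx(0.9, abs=1e-12)


def test_spectral_identities_randomized():
    """P(q) = 0; the exchange identities r_j + delta_j q_i = r_H (exact when
    the diffusion contribution drops, i.e. rho = 0 or d1 = d2, and with the
    d_j rho^2 shift in general); the Hamiltonian decomposition; agreement
    with a dense 2x2 eigensolver."""
    rng = np.random.default_rng(42)
    r1, r2, e1, e2, d1, d2, rho, N = _sample(rng, 500)
    for k in range(500):
        f = flat(r1[k], r2[k], e1[k], e2[k])
        for rho_k, dd1, dd2 in ((rho[k], d1[k], d2[k]),
                                (0.0, d1[k], d2[k]),
                                (rho[k], d1[k], d1[k] if d1[k] else 1.0)):
            diff = DiffusionPair(dd1, dd2)
            q1 = float(q_root(0.0, rho_k, diff, f, which=1))
            rH = float(hamiltonian_fitness(0.0, rho_k, diff, f))
            H = float(hamiltonian(rho_k, N[k], 0.0, diff, f))
            if rho_k == 0.0 or dd1 == dd2:
                # plain exchange identities (diffusion shift vanishes)
                assert r2[k] + e2[k] * q1 == pytest.approx(rH, abs=1e-10)
                assert r1[k] + e1[k] / q1 == pytest.approx(rH, abs=1e-10)
            # general form: both shifted identities give the eigenvalue
            lhs1 = r2[k] + dd2 * rho_k ** 2 + e2[k] * q1
            lhs2 = r1[k] + dd1 * rho_k ** 2 + e1[k] / q1
            assert lhs1 == pytest.approx(H + N[k], abs=1e-10)
            assert lhs2 == pytest.approx(H + N[k], abs=1e-10)
            # decomposition
            assert H == pytest.approx(
                0.5 * (dd1 + dd2) * rho_k ** 2 + rH - N[k], abs=1e-12)
            # eigensolver oracle: H is the larger eigenvalue of rho^2 D + R
            A = np.array([[dd1 * rho_k ** 2 + r1[k] - N[k], e1[k]],
                          [e2[k], dd2 * rho_k ** 2 + r2[k] - N[k]]])
            lam = np.linalg.eigvals(A)
            assert H == pytest.approx(float(np.max(lam.real)), abs=1e-10)


def test_principal_eigenvector():
    rng = np.random.default_rng(3)
    r1, r2, e1, e2, d1, d2, rho, N = _sample(rng, 100)
    for k in range(100):
        f = flat(r1[k], r2[k], e1[k], e2[k])
        diff = DiffusionPair(d1[k], d2[k])
        sp = principal_eigenvector(0.0, rho[k], diff, f, N[k])
        assert sp.psi[0] == 1.0
        assert sp.psi[1] > 0
        scale = max(1.0, abs(sp.eigenvalue))
        assert sp.residual <= 1e-10 * scale
        # collinear with the eigensolver's positive eigenvector
        A = np.array([[d1[k] * rho[k] ** 2 + r1[k] - N[k], e1[k]],
                      [e2[k], d2[k] * rho[k] ** 2 + r2[k] - N[k]]])
        lam, vecs = np.linalg.eig(A)
        v = vecs[:, np.argmax(lam.real)].real
        v = v / v[0]
        assert sp.psi[1] == pytest.approx(v[1], rel=1e-8)


def test_symmetric_system_eigenvector_is_flat():
    f = flat(0.8, 0.8, 0.1, 0.1)
    sp = principal_eigenvector(0.0, 0.4, DiffusionPair(1, 1), f, 0.5)
    assert sp.psi == pytest.approx((1.0, 1.0))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(r1=st.floats(-1, 2), r2=st.floats(-1, 2),
       e1=st.floats(1e-6, 1), e2=st.floats(1e-6, 1),
       d1=st.floats(0, 2), d2=st.floats(0.01, 2), rho=st.floats(0, 3))
def test_q_positive_root_property(r1, r2, e1, e2, d1, d2, rho):
    f = flat(r1, r2, e1, e2)
    q = float(q_root(0.0, rho, DiffusionPair(d1, d2), f))
    assert q > 0
    b = (d1 - d2) * rho ** 2 + (r1 - r2)
    P = e1 + b * q - e2 * q ** 2
    assert abs(P) <= 1e-10 * max(1.0, e2 * q ** 2)


# -------------------------------------------------------- r_inf and peaks ----

def test_r_inf_constant_field_average():
    f = flat(0.9, 0.9, 0.08, 0.08)
    r_inf = effective_fitness_r_inf(NODES, f)
    assert np.allclose(r_inf, 0.9 + 0.08, atol=1e-14)


def test_r_inf_equals_r_H_nodewise(field_x_coarse, coarse_grid):
    prof = fitness_profile(coarse_grid, field_x_coarse, DiffusionPair(1, 1),
                           rho=0.7)
    assert np.max(np.abs(prof.r_inf - prof.r_H)) < 1e-12


def test_r_inf_weighted_average_evaluated_independently(field_x_coarse,
                                                       coarse_grid):
    f = field_x_coarse
    # independent elementwise evaluation of the weighted-average form
    gap = f.r1 - f.r2
    q = (gap + np.sqrt(gap ** 2 + 4 * f.delta1 * f.delta2)) / (2 * f.delta2)
    expected = q / (1 + q) * (f.r1 + f.delta2) + 1 / (1 + q) * (f.r2 + f.delta1)
    assert np.allclose(effective_fitness_r_inf(coarse_grid, f), expected,
                       atol=1e-13)


def test_argmax_parabola():
    x = np.linspace(0, 6, 601)
    prof_y = 1 - (x - 3.001) ** 2
    res = argmax_fitness((x, prof_y))
    assert res.trait == pytest.approx(3.001, abs=1e-6)
    assert not res.on_boundary and not res.flat


def test_argmax_monotone_boundary_and_flat():
    x = np.linspace(0, 6, 61)
    res = argmax_fitness((x, 0.1 * x))
    assert res.on_boundary and res.trait == pytest.approx(6.0)
    res = argmax_fitness((x, np.ones_like(x)))
    assert res.flat and res.trait == pytest.approx(0.0)  # leftmost tie rule


def test_argmax_stable_under_grid_doubling(bio_x):
    res = []
    for M in (601, 1201):
        grid = np.linspace(0, 12, M)
        f = effective_coefficients(grid, bio_x)
        prof = fitness_profile(grid, f)
        r = argmax_fitness(prof)
        assert not r.on_boundary
        res.append(r.trait)
    assert res[0] == pytest.approx(res[1], abs=0.01)
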