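"""Rates, survival kernel and effective coefficients.

The independent oracle throughout is scipy's adaptive quadrature
(`scipy.integrate.quad`), which evaluates the cumulative integrals and the
outer fate integrals without using the package's closed forms or fixed-grid
Simpson rule.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from dnadapt import (
    AssumptionError, BioParams, CoefficientField, Environment,
    adaptation_rate, damaged_density, effective_coefficients, repair_rate,
    survival_kernel, validate_assumptions,
)

ENV_HALF = Environment(mode="constant", level=0.5)


# ---------------------------------------------------------------- oracle ----

def _alpha(s, bio):
    return bio.alpha_m * math.exp(-((s - bio.mu_a) ** 2) / (2 * bio.sigma))


def _beta(s, x, p, bio):
    return bio.beta_m / (1.0 + math.exp(-p * (s - x)))


def kernel_oracle(trait, s, bio, tol=1e-12):
    """Survival kernel via adaptive quadrature of both cumulative rates."""
    if bio.trait_mode == "timing_x":
        x, p = trait, bio.fixed_trait
    else:
        x, p = bio.fixed_trait, trait
    ia, _ = quad(_alpha, 0, s, args=(bio,), epsabs=tol, epsrel=tol, limit=500)
    ib, _ = quad(_beta, 0, s, args=(x, p, bio), epsabs=tol, epsrel=tol, limit=500)
    return math.exp(-bio.gamma_d * s - ia - ib)


def fate_integrals_oracle(trait, bio, s_max=280.0, tol=1e-10):
    """(P_repair, P_adapt) via nested adaptive quadrature."""
    if bio.trait_mode == "timing_x":
        x, p = trait, bio.fixed_trait
    else:
        x, p = bio.fixed_trait, trait

    def f_rep(s):
        return _alpha(s, bio) * kernel_oracle(trait, s, bio)

    def f_ad(s):
        return _beta(s, x, p, bio) * kernel_oracle(trait, s, bio)

    pr, _ = quad(f_rep, 0, s_max, epsabs=tol, epsrel=tol, limit=500)
    pa, _ = quad(f_ad, 0, s_max, epsabs=tol, epsrel=tol, limit=500)
    return pr, pa


# ----------------------------------------------------------------- rates ----

def test_repair_rate_examples(bio_x):
    # Gaussian peak at s = mu_a, zero environment, and a plain substitution
    assert repair_rate(1.0, 0.0, ENV_HALF, bio_x) == pytest.approx(0.5)
    env0 = Environment(mode="constant", level=0.0)
    s = np.linspace(0, 10, 11)
    assert np.all(repair_rate(s, 0.0, env0, bio_x) == 0)
    assert repair_rate(2.0, 0.0, ENV_HALF, bio_x) == pytest.approx(0.5 * math.exp(-1))
    assert np.all(repair_rate(s, 3.0, ENV_HALF, bio_x) <= bio_x.alpha_m)


def test_repair_rate_domain_errors(bio_x):
    with pytest.raises(ValueError):
        repair_rate(-0.1, 0.0, ENV_HALF, bio_x)
    with pytest.raises(ValueError):
        repair_rate(0.1, -1.0, ENV_HALF, bio_x)
    with pytest.raises(ValueError):
        repair_rate(0.1, 0.0, Environment(level=0.9), bio_x)  # exceeds alpha_m


def test_adaptation_rate_examples():
    bio = BioParams.timing(p_bar=3.0)
    # logistic midpoint at s = x
    assert adaptation_rate(4.0, 4.0, bio) == pytest.approx(0.25)
    # flat logistic at p = 0
    flat = BioParams.timing(p_bar=0.0)
    assert adaptation_rate(4.0, 7.3, flat) == pytest.approx(0.25)
    # saturation
    assert adaptation_rate(4.0, 1e3, bio) == pytest.approx(0.5, abs=1e-12)
    # strictly increasing in s for p > 0 (before saturation to 1 ulp)
    s = np.linspace(0, 8, 200)
    vals = adaptation_rate(4.0, s, bio)
    assert np.all(np.diff(vals) > 0)
    assert np.all((vals > 0) & (vals < bio.beta_m))


def test_adaptation_rate_heterogeneity_mode():
    bio = BioParams.heterogeneity(x_bar=4.0)
    # trait is now the steepness p; midpoint still at s = x_bar
    assert adaptation_rate(3.0, 4.0, bio) == pytest.approx(0.25)
    assert adaptation_rate(0.0, 100.0, bio) == pytest.approx(0.25)


def test_survival_kernel_basic(bio_x):
    assert survival_kernel(4.0, 0.0, bio_x) == pytest.approx(1.0)
    s = np.linspace(0, 60, 400)
    k = survival_kernel(4.0, s, bio_x)
    assert np.all(np.diff(k) <= 0)
    assert np.all(k <= np.exp(-bio_x.gamma_d * s) + 1e-15)


def test_survival_kernel_matches_adaptive_quadrature(bio_x, bio_p):
    for bio, trait in [(bio_x, 4.0), (bio_x, 1.3), (bio_p, 2.0)]:
        for s in (0.7, 3.0, 9.0):
            assert survival_kernel(trait, s, bio) == pytest.approx(
                kernel_oracle(trait, s, bio), abs=1e-8)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(trait=st.floats(0.0, 12.0), s1=st.floats(0.0, 30.0),
       ds=st.floats(0.0, 30.0), p_mode=st.booleans())
def test_kernel_monotone_and_dominated(trait, s1, ds, p_mode):
    bio = BioParams.heterogeneity(4.0) if p_mode else BioParams.timing(3.0)
    k1 = survival_kernel(trait, s1, bio)
    k2 = survival_kernel(trait, s1 + ds, bio)
    assert k2 <= k1 * (1 + 1e-12)
    assert k1 <= math.exp(-bio.gamma_d * s1) * (1 + 1e-12)


def test_damaged_density(bio_x):
    n = 0.7
    assert damaged_density(4.0, 0.0, n, bio_x) == pytest.approx(
        bio_x.damage_rate * n)
    assert damaged_density(4.0, 2.0, 0.0, bio_x) == 0.0
    bio0 = BioParams.timing(p_bar=3.0, damage_rate=0.0)
    assert damaged_density(4.0, 2.0, n, bio0) == 0.0


# ------------------------------------------------- effective coefficients ----

def test_effective_coefficients_trivial_structure(coarse_grid):
    bio0 = BioParams.timing(p_bar=3.0, damage_rate=0.0)
    f = effective_coefficients(coarse_grid, bio0)
    assert np.allclose(f.r1, 1.0, atol=1e-14)
    assert np.allclose(f.delta2, 0.0, atol=1e-14)
    bio = BioParams.timing(p_bar=3.0, delta=0.07)
    f = effective_coefficients(np.linspace(0, 12, 25), bio)
    assert np.allclose(f.r2, 1 - 0.35 - 0.07)
    assert np.allclose(f.delta1, 0.07)


def test_probability_conservation(field_x_coarse):
    # repair + adaptation + death probabilities of a damaged cell sum to 1
    assert field_x_coarse.conservation_error.max() < 1e-8
    assert np.all(field_x_coarse.delta2 <= field_x_coarse.bio.damage_rate)
    assert np.all(field_x_coarse.repair_prob <= 1.0)


def test_effective_coefficients_match_nested_quadrature(bio_x):
    f = effective_coefficients(np.array([4.0]), bio_x)
    pr, pa = fate_integrals_oracle(4.0, bio_x)
    D = bio_x.damage_rate
    assert f.r1[0] == pytest.approx(1 - D + D * pr, abs=1e-6)
    assert f.delta2[0] == pytest.approx(D * pa, abs=1e-6)


def test_quadrature_refinement_stability(bio_x):
    nodes = np.linspace(0, 12, 13)
    f1 = effective_coefficients(nodes, bio_x, ds=0.02)
    f2 = effective_coefficients(nodes, bio_x, ds=0.01)
    assert np.max(np.abs(f1.r1 - f2.r1)) < 1e-8
    assert np.max(np.abs(f1.delta2 - f2.delta2)) < 1e-8


def test_tail_bound_enforced(bio_x):
    with pytest.raises(ValueError, match="s_max"):
        effective_coefficients(np.linspace(0, 12, 5), bio_x, s_max=50.0)


# ---------------------------------------------------------- assumptions ----

def test_validate_assumptions_constant_field():
    nodes = np.linspace(0, 12, 11)
    f = CoefficientField.constant(nodes, 1.0, 1.0, 0.1, 0.1)
    rep = validate_assumptions(f)
    assert rep.c_N == pytest.approx(1.1)
    assert rep.C_N == pytest.approx(1.1)


def test_validate_assumptions_defaults_within_bracket(field_x_coarse):
    rep = validate_assumptions(field_x_coarse)
    assert rep.c_N_closed <= rep.c_N + 1e-12
    assert rep.C_N <= rep.C_N_closed + 1e-12
    assert rep.C_N_closed == pytest.approx(2.3)
    assert rep.c_N == pytest.approx(0.65)  # limited by r2 + delta1 = 1 - gamma_a


def test_validate_assumptions_rejects_vanishing_exchange():
    nodes = np.linspace(0, 12, 11)
    d2 = np.full(11, 0.1)
    d2[3] = 0.0
    f = CoefficientField.from_arrays(nodes, 1.0, 1.0, 0.1, d2)
    with pytest.raises(AssumptionError):
        validate_assumptions(f)


def test_bioparams_invariants():
    with pytest.raises(ValueError):
        BioParams(damage_rate=1.0)
    with pytest.raises(ValueError):
        BioParams(gamma_a=1.2)
    with pytest.raises(ValueError):
        BioParams(sigma=0.0)
    with pytest.raises(ValueError):
        Environment(mode="cosine_power", exponent=7)
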