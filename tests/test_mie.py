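"""Mie core: special functions, coefficients, angle functions, Mueller elements."""

import math

import mpmath as mp
import numpy as np
import pytest

from cplscat.mie import (
    OpticalContext,
    amplitude_functions,
    angular_functions,
    mie_coefficients,
    mueller_elements,
    riccati_bessel,
    wiscombe_nmax,
)

mp.mp.dps = 40


# ---------------------------------------------------------------- oracles

def _psi_mp(n, z):
    return mp.sqrt(mp.pi * z / 2) * mp.besselj(n + mp.mpf("0.5"), z)


def _chi_mp(n, z):
    return -mp.sqrt(mp.pi * z / 2) * mp.bessely(n + mp.mpf("0.5"), z)


def _dpsi_mp(n, z):
    return _psi_mp(n - 1, z) - n * _psi_mp(n, z) / z


def _xi_mp(n, z):
    return _psi_mp(n, z) + 1j * _chi_mp(n, z)


def _dxi_mp(n, z):
    return _xi_mp(n - 1, z) - n * _xi_mp(n, z) / z


def _mie_ab_direct(m, x, n):
    """Brute-force Mie coefficient of order n by direct high-precision Bessel
    evaluation of the defining ratios (no recurrences)."""
    m = mp.mpf(m)
    x = mp.mpf(x)
    mx = m * x
    a = (m * _psi_mp(n, mx) * _dpsi_mp(n, x) - _psi_mp(n, x) * _dpsi_mp(n, mx)) / (
        m * _psi_mp(n, mx) * _dxi_mp(n, x) - _xi_mp(n, x) * _dpsi_mp(n, mx)
    )
    b = (_psi_mp(n, mx) * _dpsi_mp(n, x) - m * _psi_mp(n, x) * _dpsi_mp(n, mx)) / (
        _psi_mp(n, mx) * _dxi_mp(n, x) - m * _xi_mp(n, x) * _dpsi_mp(n, mx)
    )
    return complex(a), complex(b)


# ---------------------------------------------------------- OpticalContext

def test_optical_context_derived_quantities():
    ctx = OpticalContext(wavelength_nm=1000.0, diameter_um=9.0)
    assert ctx.X == pytest.approx(9.0)
    assert ctx.x == pytest.approx(math.pi * 9.0 * 1.33)
    assert round(ctx.m, 3) == 1.195
    cell = OpticalContext(1000.0, 9.0, n_particle=1.39, n_medium=1.37)
    assert round(cell.m, 3) == 1.015


@pytest.mark.parametrize("field,value", [
    ("wavelength_nm", -1.0), ("diameter_um", 0.0), ("n_medium", float("nan")),
])
def test_optical_context_rejects_bad_inputs(field, value):
    kwargs = {"wavelength_nm": 1000.0, "diameter_um": 9.0}
    kwargs[field] = value
    with pytest.raises(ValueError):
        OpticalContext(**kwargs)


# ---------------------------------------------------------- Riccati-Bessel

def test_riccati_psi1_closed_form():
    psi, _, _, _ = riccati_bessel(2.0, 2)
    assert psi[1] == pytest.approx(math.sin(2) / 2 - math.cos(2), rel=1e-12)


def test_riccati_agrees_with_high_precision_oracle():
    x = 10.0
    n_max = wiscombe_nmax(x)
    psi, dpsi, xi, dxi = riccati_bessel(x, n_max)
    for n in range(1, n_max + 1):
        assert psi[n] == pytest.approx(float(_psi_mp(n, x)), rel=1e-10, abs=1e-25)
        assert dpsi[n] == pytest.approx(float(_dpsi_mp(n, x)), rel=1e-10, abs=1e-25)
        ref_xi = complex(_xi_mp(n, x))
        assert xi[n] == pytest.approx(ref_xi, rel=1e-10)
        assert dxi[n] == pytest.approx(complex(_dxi_mp(n, x)), rel=1e-10)


@pytest.mark.parametrize("x", [0.5, 1.0, 5.0, 20.0])
def test_riccati_hankel_relation(x):
    """xi_n - psi_n = -i x y_n(x) holds definitionally on a grid of arguments."""
    from scipy.special import spherical_yn

    n_max = 8
    psi, _, xi, _ = riccati_bessel(x, n_max)
    n = np.arange(n_max + 1)
    np.testing.assert_allclose(
        xi - psi, -1j * x * spherical_yn(n, x), rtol=1e-12, atol=1e-14
    )


def test_riccati_complex_argument_matches_oracle():
    z = 3.0 + 0.4j
    psi, dpsi, xi, dxi = riccati_bessel(z, 6)
    for n in (1, 3, 6):
        assert psi[n] == pytest.approx(complex(_psi_mp(n, mp.mpc(z))), rel=1e-9)
        assert xi[n] == pytest.approx(complex(_xi_mp(n, mp.mpc(z))), rel=1e-9)
        assert dpsi[n] == pytest.approx(complex(_dpsi_mp(n, mp.mpc(z))), rel=1e-9)
        assert dxi[n] == pytest.approx(complex(_dxi_mp(n, mp.mpc(z))), rel=1e-9)


def test_riccati_rejects_bad_arguments():
    with pytest.raises(ValueError):
        riccati_bessel(float("nan"), 3)
    with pytest.raises(ValueError):
        riccati_bessel(0.0, 3)


# ------------------------------------------------------- Mie coefficients

def test_rayleigh_limit_of_a1():
    """a_1 -> (2i/3) x^3 (m^2-1)/(m^2+2) as x -> 0.

    The sign follows the xi_n = x(j_n - i y_n) convention used throughout;
    with the conjugate (h1-based) convention a_1 would be its conjugate.
    """
    m, x = 1.195, 1e-3
    ser = mie_coefficients(m, x, n_max=2)
    closed = 2j / 3 * x**3 * (m**2 - 1) / (m**2 + 2)
    assert ser.a_n[0] == pytest.approx(closed, rel=1e-6)


def test_index_matched_sphere_scatters_nothing():
    with pytest.warns(UserWarning):
        ser = mie_coefficients(1.0, 5.0)
    assert np.all(ser.a_n == 0) and np.all(ser.b_n == 0)


def test_coefficients_match_brute_force_oracle():
    """Full series at the X=9 study point against non-recursive evaluation."""
    m, x = 1.195, math.pi * 9.0 * 1.33
    ser = mie_coefficients(m, x)
    for n in range(1, ser.order_max + 1):
        a_ref, b_ref = _mie_ab_direct(m, x, n)
        assert ser.a_n[n - 1] == pytest.approx(a_ref, rel=1e-9, abs=1e-13)
        assert ser.b_n[n - 1] == pytest.approx(b_ref, rel=1e-9, abs=1e-13)


def test_coefficients_passive_and_decaying():
    for x in (0.5, 5.0, 40.0):
        ser = mie_coefficients(1.5, x)
        assert np.all(np.abs(ser.a_n) <= 1 + 1e-10)
        assert np.all(np.abs(ser.b_n) <= 1 + 1e-10)
        assert ser.tail_magnitude() < 1e-6


# -------------------------------------------------------- angle functions

def test_angular_function_seeds():
    ang = angular_functions(0.7, 3)
    assert ang.pi_n[0, 0] == pytest.approx(1.0)
    assert ang.tau_n[0, 0] == pytest.approx(math.cos(0.7))


@pytest.mark.parametrize("theta", [0.0, math.pi])
def test_angular_functions_at_poles(theta):
    """pi_n(0) = tau_n(0) = n(n+1)/2 and pi_n(pi) = -tau_n(pi) = (-1)^(n+1) n(n+1)/2.

    Oracle: direct associated-Legendre evaluation P_n^1(cos t)/sin t just off
    the pole (scipy's lpmv carries the Condon-Shortley phase, hence the sign).
    """
    from scipy.special import lpmv

    ang = angular_functions(theta, 10)
    eps = 1e-5
    t = eps if theta == 0.0 else math.pi - eps
    for n in range(1, 11):
        pi_ref = -lpmv(1, n, math.cos(t)) / math.sin(t)
        if theta == 0.0:
            pi_exp = n * (n + 1) / 2
            tau_exp = pi_exp
        else:
            pi_exp = (-1.0) ** (n + 1) * n * (n + 1) / 2
            tau_exp = -pi_exp
        assert pi_ref == pytest.approx(pi_exp, rel=1e-5)  # oracle sanity
        assert ang.pi_n[n - 1, 0] == pytest.approx(pi_exp, rel=1e-12)
        assert ang.tau_n[n - 1, 0] == pytest.approx(tau_exp, rel=1e-12)


def test_angular_functions_reject_out_of_range():
    with pytest.raises(ValueError):
        angular_functions(-0.1, 3)
    with pytest.raises(ValueError):
        angular_functions(3.5, 3)


# ------------------------------------------------------------- amplitudes

def test_amplitude_forward_equality_and_backward_antisymmetry():
    m, x = 1.195, 20.0
    ser = mie_coefficients(m, x)
    amp = amplitude_functions(m, x, np.array([0.0, np.pi]))
    n = np.arange(1, ser.order_max + 1)
    forward = np.sum((2 * n + 1) * (ser.a_n + ser.b_n)) / 2
    assert amp.s1[0] == pytest.approx(amp.s2[0], rel=1e-12)
    assert amp.s1[0] == pytest.approx(forward, rel=1e-10)
    assert amp.s1[1] == pytest.approx(-amp.s2[1], rel=1e-10)


def test_amplitudes_converged_against_extended_series():
    """|S1|^2, |S2|^2 stable against a 4x over-truncated direct sum."""
    m, x = 1.195, 20.0
    theta = np.linspace(0.0, np.pi, 91)
    amp = amplitude_functions(m, x, theta)
    big = amplitude_functions(m, x, theta, n_max=4 * wiscombe_nmax(x))
    scale = np.max(np.abs(big.s1) ** 2)
    np.testing.assert_allclose(
        np.abs(amp.s1) ** 2 / scale, np.abs(big.s1) ** 2 / scale, atol=1e-8
    )
    np.testing.assert_allclose(
        np.abs(amp.s2) ** 2 / scale, np.abs(big.s2) ** 2 / scale, atol=1e-8
    )


# -------------------------------------------------------- Mueller elements

def test_mueller_pure_identity_random_draws():
    """M11^2 = M12^2 + M33^2 + M34^2 across the full (m, x, theta) domain."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        m = rng.uniform(1.01, 2.0)
        x = rng.uniform(0.1, 40.0)
        theta = rng.uniform(0.0, np.pi, 25)
        el = mueller_elements(m, x, theta)
        lhs = el.m11**2
        rhs = el.m12**2 + el.m33**2 + el.m34**2
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)
        assert np.all(el.m11 >= 0)
        assert np.all(np.abs(el.m12) <= el.m11 * (1 + 1e-12))


def test_mueller_forward_backward_circular_limits():
    for m, x in [(1.1, 3.0), (1.195, 37.6), (1.8, 12.0)]:
        el = mueller_elements(m, x, np.array([0.0, np.pi]))
        assert el.m33[0] / el.m11[0] == pytest.approx(1.0, abs=1e-12)
        assert el.m33[1] / el.m11[1] == pytest.approx(-1.0, abs=1e-12)
        assert el.m12[0] == pytest.approx(0.0, abs=el.m11[0] * 1e-12)


def test_mueller_rayleigh_limit_circular_ratio():
    theta = np.linspace(0.01, np.pi - 0.01, 200)
    el = mueller_elements(1.195, 1e-2, theta)
    expected = 2 * np.cos(theta) / (1 + np.cos(theta) ** 2)
    np.testing.assert_allclose(el.m33 / el.m11, expected, atol=1e-4)


def test_mueller_continuity_toward_index_matching():
    theta = np.linspace(0.0, np.pi, 50)
    prev = None
    for m in (1.1, 1.01, 1.001):
        el = mueller_elements(m, 5.0, theta)
        peak = float(np.max(el.m11))
        if prev is not None:
            assert peak < prev * 0.3  # amplitude dies smoothly as m -> 1
        prev = peak


def test_series_convergence_when_truncation_doubled():
    m, x = 1.195, 37.6
    theta = np.linspace(0.0, np.pi, 181)
    el = mueller_elements(m, x, theta)
    el2 = mueller_elements(m, x, theta, n_max=2 * wiscombe_nmax(x))
    scale = np.max(el.m11)
    np.testing.assert_allclose(el.m11 / scale, el2.m11 / scale, atol=1e-8)
    np.testing.assert_allclose(el.m33 / scale, el2.m33 / scale, atol=1e-8)
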