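"""Exact single-sphere Mie scattering quantities.

This module computes the ingredients of Lorenz–Mie theory for a homogeneous
sphere embedded in a non-absorbing medium: Riccati–Bessel functions, the Mie
expansion coefficients a_n and b_n, the angle-dependent functions pi_n and
tau_n, the complex scattering amplitudes S1(theta) and S2(theta), and the four
independent elements of the single-sphere (block-diagonal) Mueller matrix,

    M11 = (|S2|^2 + |S1|^2)/2,   M12 = (|S2|^2 - |S1|^2)/2,
    M33 = Re(S2 S1*),            M34 = Im(S2 S1*),

with S1 the amplitude perpendicular and S2 parallel to the scattering plane.
Everything is a function of the relative refractive index m = n_particle /
n_medium and the size parameter x = pi * a * n_medium / lambda, where a is
the particle *diameter* (so x coincides with the conventional radius-based
2*pi*r*n/lambda).

The degree of circular polarization transferred by one scattering event is
M33/M11, which is exactly +1 at theta=0 and -1 at theta=pi for every (m, x):
forward scattering preserves helicity, direct backscattering flips it.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import special

__all__ = [
    "OpticalContext",
    "MieCoefficientSeries",
    "AngularFunctions",
    "ScatteringAmplitudes",
    "MuellerElements",
    "wiscombe_nmax",
    "riccati_bessel",
    "mie_coefficients",
    "angular_functions",
    "amplitude_functions",
    "mueller_elements",
    "default_theta_grid",
]


@dataclasses.dataclass(frozen=True)
class OpticalContext:
    """Wavelength, particle diameter and refractive indices of one scattering problem.

    Parameters
    ----------
    wavelength_nm : float
        Vacuum wavelength of the light in nanometres.
    diameter_um : float
        Particle diameter ``a`` in micrometres.
    n_particle, n_medium : float
        Refractive indices of the particle and the host medium.  The defaults
        (1.59, 1.33) are typical of organic particles in water.

    Derived quantities
    ------------------
    ``m`` — relative refractive index n_particle/n_medium;
    ``x`` — Mie size parameter pi*a*n_medium/lambda;
    ``X`` — generalized size parameter a/lambda (diameter over wavelength,
    both in the same units), the natural axis of depolarization diagrams.
    """

    wavelength_nm: float
    diameter_um: float
    n_particle: float = 1.59
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "diameter_um", "n_particle", "n_medium"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def m(self) -> float:
        return self.n_particle / self.n_medium

    @property
    def x(self) -> float:
        # diameter in nm over wavelength in nm; dimensionless
        return math.pi * (self.diameter_um * 1000.0) * self.n_medium / self.wavelength_nm

    @property
    def X(self) -> float:
        return (self.diameter_um * 1000.0) / self.wavelength_nm


@dataclasses.dataclass(frozen=True)
class MieCoefficientSeries:
    """Mie expansion coefficients a_n, b_n for n = 1..order_max.

    ``a_n[k]`` holds the coefficient of order ``k+1``.  For real relative
    index the coefficients are passive, |a_n| <= 1 and |b_n| <= 1.
    """

    order_max: int
    a_n: np.ndarray
    b_n: np.ndarray
    m: complex = dataclasses.field(default=1.0, repr=False)
    x: float = dataclasses.field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        if self.order_max < 1:
            raise ValueError("order_max must be >= 1")
        if len(self.a_n) != self.order_max or len(self.b_n) != self.order_max:
            raise ValueError("coefficient arrays must have length order_max")
        if not (np.all(np.isfinite(self.a_n)) and np.all(np.isfinite(self.b_n))):
            raise FloatingPointError("non-finite Mie coefficients (series truncation error)")
        # passivity holds exactly for non-absorbing spheres (real m)
        if abs(complex(self.m).imag) == 0.0:
            tol = 1.0 + 1e-10
            if np.any(np.abs(self.a_n) > tol) or np.any(np.abs(self.b_n) > tol):
                raise FloatingPointError("|a_n|,|b_n| must not exceed 1 for real m")

    def tail_magnitude(self) -> float:
        """|a_nmax| + |b_nmax| relative to the largest term — truncation diagnostic."""
        peak = max(np.abs(self.a_n).max(), np.abs(self.b_n).max())
        return float((abs(self.a_n[-1]) + abs(self.b_n[-1])) / peak)


@dataclasses.dataclass(frozen=True)
class AngularFunctions:
    """pi_n(theta), tau_n(theta) for n = 1..n_max; row k is order k+1."""

    theta: np.ndarray
    pi_n: np.ndarray
    tau_n: np.ndarray


@dataclasses.dataclass(frozen=True)
class ScatteringAmplitudes:
    """Complex amplitudes at scattering angle theta.

    ``s1`` multiplies the field component perpendicular to the scattering
    plane, ``s2`` the parallel component.  At theta=0 the two are equal.
    """

    theta: np.ndarray
    s1: np.ndarray
    s2: np.ndarray


@dataclasses.dataclass(frozen=True)
class MuellerElements:
    """The four independent sphere Mueller elements sampled on a theta grid.

    Satisfies m11 >= 0 and the pure-Mueller identity
    m11^2 = m12^2 + m33^2 + m34^2 (single deterministic scatterer).
    """

    theta: np.ndarray
    m11: np.ndarray
    m12: np.ndarray
    m33: np.ndarray
    m34: np.ndarray


def wiscombe_nmax(x: float) -> int:
    """Series truncation order: ceil(x + 4.05 x^(1/3) + 2) (Wiscombe's rule)."""
    if x <= 0 or not math.isfinite(x):
        raise ValueError(f"size parameter must be finite and > 0, got {x!r}")
    return int(math.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


def riccati_bessel(z: complex | float, n_max: int):
    """Riccati–Bessel functions psi_n, xi_n and derivatives for n = 0..n_max.

    psi_n(z) = z j_n(z) and xi_n(z) = z (j_n(z) - i y_n(z)) with j_n, y_n the
    spherical Bessel functions; xi_n is the Riccati–Hankel function of the
    second-kind-conjugate convention used in the Mie coefficient formulas.

    Returns ``(psi, dpsi, xi, dxi)`` — arrays of length n_max+1 indexed by
    order, complex for complex ``z``.  Real arguments use scipy's spherical
    Bessel routines; complex arguments use Miller's downward recurrence for
    j_n (normalized at order 0) and upward recurrence for y_n.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    zc = complex(z)
    if not (math.isfinite(zc.real) and math.isfinite(zc.imag)) or abs(zc) == 0.0:
        raise ValueError(f"argument must be finite and non-zero, got {z!r}")

    n = np.arange(n_max + 1)
    if zc.imag == 0.0:
        xr = zc.real
        j = special.spherical_jn(n, xr)
        dj = special.spherical_jn(n, xr, derivative=True)
        y = special.spherical_yn(n, xr)
        dy = special.spherical_yn(n, xr, derivative=True)
        psi = xr * j
        dpsi = j + xr * dj
        h = j - 1j * y
        xi = xr * h
        dxi = h + xr * (dj - 1j * dy)
    else:
        j = _spherical_jn_complex(zc, n_max)
        y = _spherical_yn_complex(zc, n_max)
        psi = zc * j
        h = j - 1j * y
        xi = zc * h
        # d/dz [z f_n(z)] = z f_{n-1}(z) - n f_n(z)  for n >= 1
        dpsi = np.empty(n_max + 1, dtype=complex)
        dxi = np.empty(n_max + 1, dtype=complex)
        dpsi[0] = np.cos(zc)
        dxi[0] = np.cos(zc) + 1j * np.sin(zc)
        dpsi[1:] = psi[:-1] - n[1:] * j[1:]
        dxi[1:] = xi[:-1] - n[1:] * h[1:]

    for arr in (psi, dpsi, xi, dxi):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                "Riccati–Bessel overflow at large order (series truncation error)"
            )
    return psi, dpsi, xi, dxi


def _spherical_jn_complex(z: complex, n_max: int) -> np.ndarray:
    """j_n(z) for complex z by Miller's downward recurrence, normalized at j_0."""
    n_start = n_max + 15 + int(abs(z))
    jm = np.zeros(n_start + 2, dtype=complex)
    jm[n_start + 1] = 0.0
    jm[n_start] = 1e-30
    for k in range(n_start, 0, -1):
        jm[k - 1] = (2 * k + 1) / z * jm[k] - jm[k + 1]
    scale = (np.sin(z) / z) / jm[0]
    return jm[: n_max + 1] * scale


def _spherical_yn_complex(z: complex, n_max: int) -> np.ndarray:
    """y_n(z) for complex z by (stable) upward recurrence."""
    y = np.empty(n_max + 1, dtype=complex)
    y[0] = -np.cos(z) / z
    if n_max >= 1:
        y[1] = -np.cos(z) / z**2 - np.sin(z) / z
    for k in range(2, n_max + 1):
        y[k] = (2 * k - 1) / z * y[k - 1] - y[k - 2]
    return y


def mie_coefficients(
    m: complex | float, x: float, n_max: int | None = None
) -> MieCoefficientSeries:
    """Mie coefficients a_n, b_n for relative index ``m`` and size parameter ``x``.

    Uses the logarithmic derivative D_n(mx) computed by downward recurrence
    (started well above the truncation order) together with upward recurrence
    for psi_n(x) and chi_n(x); this is the numerically stable route for large
    size parameters.  ``n_max=None`` applies Wiscombe's truncation rule.

    ``m == 1`` is index matching: the sphere is optically absent and the
    coefficients vanish identically (returned as a zero series with a warning
    rather than hitting 0/0 in the formulas).
    """
    if not (math.isfinite(x) and x > 0):
        raise ValueError(f"size parameter must be finite and > 0, got {x!r}")
    mc = complex(m)
    if n_max is None:
        n_max = wiscombe_nmax(x)
    if mc == 1.0 + 0.0j:
        warnings.warn("m=1 scatters nothing; returning a zero coefficient series")
        z = np.zeros(n_max, dtype=complex)
        return MieCoefficientSeries(n_max, z, z.copy(), m=mc, x=x)

    mx = mc * x
    # logarithmic derivative D_n(mx) by downward recurrence
    n_start = max(n_max, int(abs(mx))) + 16
    D = np.zeros(n_start + 1, dtype=complex)
    for k in range(n_start, 0, -1):
        D[k - 1] = k / mx - 1.0 / (D[k] + k / mx)

    n = np.arange(1, n_max + 1)
    psi, dpsi, xi, dxi = riccati_bessel(x, n_max)
    psi_n, psi_nm1 = psi[1:], psi[:-1]
    xi_n, xi_nm1 = xi[1:], xi[:-1]
    Dn = D[1 : n_max + 1]

    fa = Dn / mc + n / x
    fb = Dn * mc + n / x
    a_n = (fa * psi_n - psi_nm1) / (fa * xi_n - xi_nm1)
    b_n = (fb * psi_n - psi_nm1) / (fb * xi_n - xi_nm1)
    return MieCoefficientSeries(n_max, a_n, b_n, m=mc, x=x)


def angular_functions(theta, n_max: int) -> AngularFunctions:
    """pi_n(theta) = P_n^1(cos t)/sin t and tau_n(theta) = dP_n^1/dt for n=1..n_max.

    Computed by the standard upward recurrences
        pi_n = (2n-1)/(n-1) cos(t) pi_{n-1} - n/(n-1) pi_{n-2},
        tau_n = n cos(t) pi_n - (n+1) pi_{n-1},
    seeded with pi_0 = 0, pi_1 = 1.  Accepts scalar or array theta in [0, pi].
    """
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if np.any((th < 0) | (th > np.pi)):
        raise ValueError("theta must lie in [0, pi]")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    mu = np.cos(th)
    pi_n = np.empty((n_max, th.size))
    tau_n = np.empty((n_max, th.size))
    pi_prev = np.zeros(th.size)  # pi_0
    pi_cur = np.ones(th.size)  # pi_1
    pi_n[0] = pi_cur
    tau_n[0] = mu * pi_cur - 2.0 * pi_prev
    for k in range(2, n_max + 1):
        pi_next = (2 * k - 1) / (k - 1) * mu * pi_cur - k / (k - 1) * pi_prev
        pi_n[k - 1] = pi_next
        tau_n[k - 1] = k * mu * pi_next - (k + 1) * pi_cur
        pi_prev, pi_cur = pi_cur, pi_next
    return AngularFunctions(theta=th, pi_n=pi_n, tau_n=tau_n)


def amplitude_functions(
    m: complex | float, x: float, theta, n_max: int | None = None
) -> ScatteringAmplitudes:
    """Complex scattering amplitudes S1(theta), S2(theta).

    S1 = sum_n (2n+1)/(n(n+1)) (a_n pi_n + b_n tau_n),
    S2 = sum_n (2n+1)/(n(n+1)) (a_n tau_n + b_n pi_n).
    """
    coeffs = mie_coefficients(m, x, n_max=n_max)
    ang = angular_functions(theta, coeffs.order_max)
    n = np.arange(1, coeffs.order_max + 1)
    w = (2 * n + 1) / (n * (n + 1))
    wa = w * coeffs.a_n
    wb = w * coeffs.b_n
    s1 = wa @ ang.pi_n + wb @ ang.tau_n
    s2 = wa @ ang.tau_n + wb @ ang.pi_n
    return ScatteringAmplitudes(theta=ang.theta, s1=s1, s2=s2)


def mueller_elements(
    m: complex | float, x: float, theta, n_max: int | None = None
) -> MuellerElements:
    """The four sphere Mueller elements M11, M12, M33, M34 on a theta grid."""
    amp = amplitude_functions(m, x, theta, n_max=n_max)
    a1 = np.abs(amp.s1) ** 2
    a2 = np.abs(amp.s2) ** 2
    cross = amp.s2 * np.conj(amp.s1)
    return MuellerElements(
        theta=amp.theta,
        m11=0.5 * (a2 + a1),
        m12=0.5 * (a2 - a1),
        m33=np.real(cross),
        m34=np.imag(cross),
    )


def default_theta_grid(x: float, refine: float = 1.0) -> np.ndarray:
    """Scattering-angle grid fine enough to resolve the ~pi/x interference fringes.

    Step is min(0.1 deg, 180 deg / (20 x)) divided by ``refine``; both
    endpoints theta=0 and theta=pi are included exactly.
    """
    step_deg = min(0.1, 180.0 / (20.0 * max(x, 1e-6))) / refine
    n_pts = max(int(math.ceil(180.0 / step_deg)) + 1, 181)
    return np.linspace(0.0, np.pi, n_pts)
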