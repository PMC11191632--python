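"""Single-scattering polarimetry: angular profiles and expected S3 curves.

For circularly polarized incidence the degree of circular polarization of
light scattered once into angle theta is M33(theta)/M11(theta).  Averaging
the emitted S3 over the full sphere with the phase function as the weight
gives the expected circular polarization after one scattering event,

    <S3>(m, X) = int M33 sin(theta) dtheta / int M11 sin(theta) dtheta,

a function of the relative index m and the generalized size parameter
X = a/lambda alone.  <S3>(X) dips sharply at particular X values — those are
the sizes (relative to the wavelength) at which a single Mie scattering
already depolarizes circular light strongly, and they seed the
depolarization lines seen in multiple-scattering diagrams.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import signal

from .mie import MuellerElements, OpticalContext, default_theta_grid, mueller_elements
from .stokes import StokesVector, apply_sphere_mueller

__all__ = [
    "AngularScatterProfile",
    "ExpectedS3Curve",
    "scatter_stokes",
    "angular_profile",
    "expected_s3_single",
    "find_depolarization_minima",
]

#: default n_medium used when working directly in (m, X) coordinates
N_MEDIUM_DEFAULT = 1.33


@dataclasses.dataclass(frozen=True)
class AngularScatterProfile:
    """Relative scattered intensity and circular polarization versus angle."""

    theta: np.ndarray
    intensity: np.ndarray
    s3: np.ndarray

    def backscatter_fraction(self) -> float:
        """Fraction of scattered power emitted into the backward hemisphere."""
        total = np.trapezoid(self.intensity * np.sin(self.theta), self.theta)
        back = self.theta >= np.pi / 2
        rear = np.trapezoid(
            self.intensity[back] * np.sin(self.theta[back]), self.theta[back]
        )
        return float(rear / total)

    def forward_fraction(self, half_angle_deg: float = 5.0) -> float:
        """Fraction of scattered power within ``half_angle_deg`` of forward."""
        total = np.trapezoid(self.intensity * np.sin(self.theta), self.theta)
        cone = self.theta <= np.radians(half_angle_deg)
        fwd = np.trapezoid(
            self.intensity[cone] * np.sin(self.theta[cone]), self.theta[cone]
        )
        return float(fwd / total)


@dataclasses.dataclass(frozen=True)
class ExpectedS3Curve:
    """<S3> after one scattering, sampled over generalized size parameter X."""

    x_grid: np.ndarray
    expected_s3: np.ndarray
    m: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.x_grid) != len(self.expected_s3):
            raise ValueError("x_grid and expected_s3 must have equal length")


def scatter_stokes(s_in: StokesVector, elements: MuellerElements) -> StokesVector:
    """One scattering event: sphere Mueller matrix applied in the scattering plane.

    ``elements`` must be sampled at a single angle.
    """
    if np.size(elements.m11) != 1:
        raise ValueError("scatter_stokes expects Mueller elements at a single angle")
    vals = [
        np.asarray(getattr(elements, k)).reshape(-1)[0]
        for k in ("m11", "m12", "m33", "m34")
    ]
    out = apply_sphere_mueller(s_in.as_array(), *vals)
    return StokesVector(*out)


def angular_profile(
    ctx: OpticalContext,
    s_in: StokesVector | None = None,
    theta_grid: np.ndarray | None = None,
) -> AngularScatterProfile:
    """Angular distribution of scattered intensity and S3'/S0' for one event.

    For circular (or unpolarized) input the azimuthal symmetry of the sphere
    makes the profile a function of theta only: intensity ~ M11 and
    s3 = M33/M11 * (S3/S0 of the input).  Intensity is returned relative to
    its maximum.
    """
    if s_in is None:
        s_in = StokesVector.rcp()
    if theta_grid is None:
        theta_grid = default_theta_grid(ctx.x)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if np.any((theta_grid < 0) | (theta_grid > np.pi)):
        raise ValueError("theta grid must lie within [0, pi]")
    el = mueller_elements(ctx.m, ctx.x, theta_grid)
    s = s_in.normalized()
    out = apply_sphere_mueller(
        np.broadcast_to(s.as_array(), (theta_grid.size, 4)).copy(),
        el.m11, el.m12, el.m33, el.m34,
    )
    intensity = out[:, 0]
    s3 = out[:, 3] / intensity
    return AngularScatterProfile(
        theta=theta_grid, intensity=intensity / intensity.max(), s3=s3
    )


def expected_s3_single(
    m: float,
    X: float | None = None,
    *,
    x: float | None = None,
    n_medium: float = N_MEDIUM_DEFAULT,
    refine: float = 1.0,
) -> float:
    """Expected S3 emitted by one scattering of circularly polarized light.

    Give either the generalized size parameter ``X = a/lambda`` (converted
    with ``n_medium``) or the Mie size parameter ``x`` directly.  The ratio
    of solid-angle integrals int M33 sin dtheta / int M11 sin dtheta is
    evaluated by trapezoidal quadrature on a fringe-resolving theta grid;
    ``refine`` multiplies the grid density (used for convergence checks).
    """
    if (X is None) == (x is None):
        raise ValueError("provide exactly one of X or x")
    if x is None:
        if X <= 0:
            raise ValueError("X must be > 0")
        x = math.pi * n_medium * X
    theta = default_theta_grid(x, refine=refine)
    el = mueller_elements(m, x, theta)
    sin_t = np.sin(theta)
    num = np.trapezoid(el.m33 * sin_t, theta)
    den = np.trapezoid(el.m11 * sin_t, theta)
    if not (np.isfinite(num) and np.isfinite(den)) or den <= 0:
        raise ArithmeticError(
            f"quadrature failed at m={m}, x={x}: grid of {theta.size} points"
        )
    return float(num / den)


def find_depolarization_minima(
    curve: ExpectedS3Curve,
    prominence: float = 0.004,
    smooth_window: float = 0.3,
    min_separation: float = 2.0,
) -> list[tuple[float, float]]:
    """Locate the pronounced local minima (depolarization dips) of an <S3>(X) curve.

    An exact <S3>(X) curve carries two scales: interference fringes with
    period ~0.1-0.4 in X and amplitude up to ~0.02, riding on broad
    depolarization troughs spaced ~3-4 apart.  The detector separates them
    by (i) smoothing with a moving average of width ``smooth_window`` in X,
    (ii) requiring topographic ``prominence`` (in <S3> units) above the
    residual fringe level, and (iii) enforcing ``min_separation`` in X
    between reported minima, keeping the deepest of any closer pair — half
    the smallest physical inter-trough spacing, so fringe satellites on a
    trough's shoulders are absorbed into it.

    Returns ``(X_location, prominence)`` pairs sorted ascending in X.
    """
    xg = np.asarray(curve.x_grid, dtype=float)
    ys = np.asarray(curve.expected_s3, dtype=float)
    if xg.size == 0:
        raise ValueError("empty curve")
    if xg.size < 3:
        return []
    dx = float(np.median(np.diff(xg)))
    win = max(int(round(smooth_window / dx)), 1)
    if win % 2 == 0:
        win += 1
    if win > 1:
        kernel = np.ones(win) / win
        # reflect-pad so the ends are not dragged toward zero
        padded = np.concatenate([ys[win - 1 : 0 : -1], ys, ys[-2 : -win - 1 : -1]])
        ys = np.convolve(padded, kernel, mode="same")[win - 1 : win - 1 + xg.size]
    distance = max(int(round(min_separation / dx)), 1)
    idx, props = signal.find_peaks(-ys, prominence=prominence, distance=distance)
    return sorted(zip(xg[idx], props["prominences"]))
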