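"""Sampling of polarized single-scattering angles.

In the meridian-plane formalism a photon's Stokes vector is referenced to
the plane containing its propagation direction.  Picking the azimuth phi of
the scattering plane and the polar scattering angle theta from the polarized
phase density

    P(theta, phi) ∝ [M11(theta) S0 + M12(theta) (S1 cos 2phi + S2 sin 2phi)]
                    * sin(theta)

couples the angle statistics to the current polarization state.  Two exact
samplers are provided:

* :func:`rejection_sample_angles` — joint rejection against a global-max
  envelope (the textbook rejection method).  Robust, but for strongly
  forward-peaked Mie kernels its acceptance rate scales like the inverse
  of the forward-peak enhancement and becomes very small at large x.
* :func:`sample_theta_phi` — the transport-engine sampler: theta by
  tabulated inverse CDF of the exact marginal M11 sin(theta) (the phi
  integral of P), then phi by conditional rejection with envelope 1 + |r|,
  whose acceptance is always >= 1/2.  Draws from the identical joint
  density at bounded cost.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .mie import default_theta_grid, mueller_elements

__all__ = ["PhaseTable", "rejection_sample_angles", "sample_theta_phi"]


@dataclasses.dataclass(frozen=True)
class PhaseTable:
    """Tabulated sphere Mueller elements and sampling tables for one (m, x)."""

    m: float
    x: float
    theta: np.ndarray
    m11: np.ndarray
    m12: np.ndarray
    m33: np.ndarray
    m34: np.ndarray
    cdf: np.ndarray          # CDF of M11 sin(theta) on the theta grid
    density_max: float       # global max of (M11 + |M12|) sin(theta)
    albedo_weighted_g: float  # mean cosine of the M11 phase function

    @classmethod
    def build(cls, m: float, x: float, refine: float = 1.0) -> "PhaseTable":
        theta = default_theta_grid(x, refine=refine)
        el = mueller_elements(m, x, theta)
        sin_t = np.sin(theta)
        w = el.m11 * sin_t
        # trapezoid cumulative integral, normalized
        dth = np.diff(theta)
        seg = 0.5 * (w[1:] + w[:-1]) * dth
        cdf = np.concatenate([[0.0], np.cumsum(seg)])
        cdf /= cdf[-1]
        g = float(np.trapezoid(w * np.cos(theta), theta) / np.trapezoid(w, theta))
        dmax = float(np.max((el.m11 + np.abs(el.m12)) * sin_t))
        return cls(
            m=m, x=x, theta=theta,
            m11=el.m11, m12=el.m12, m33=el.m33, m34=el.m34,
            cdf=cdf, density_max=dmax, albedo_weighted_g=g,
        )

    def interp(self, name: str, theta: np.ndarray) -> np.ndarray:
        return np.interp(theta, self.theta, getattr(self, name))

    def sample_theta(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF draw from the marginal density M11(theta) sin(theta)."""
        return np.interp(u, self.cdf, self.theta)


def rejection_sample_angles(
    stokes,
    table: PhaseTable,
    rng: np.random.Generator,
    size: int = 1,
    max_batches: int = 10000,
):
    """Joint (theta, phi) draw by rejection against the global-max envelope.

    ``stokes`` is a normalized Stokes 4-vector (S0=1).  Raises if the running
    acceptance rate falls below 1e-3, which signals an envelope far above the
    density (pathological table or unnormalized input).
    """
    s = np.asarray(stokes, dtype=float).reshape(4)
    if not np.isclose(s[0], 1.0):
        raise ValueError("rejection sampler expects a normalized Stokes vector (S0=1)")
    out_t = np.empty(size)
    out_p = np.empty(size)
    filled = 0
    proposed = 0
    accepted = 0
    for _ in range(max_batches):
        n = max(2 * (size - filled), 1024)
        theta = rng.uniform(0.0, np.pi, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        m11 = table.interp("m11", theta)
        m12 = table.interp("m12", theta)
        dens = (m11 * s[0] + m12 * (s[1] * np.cos(2 * phi) + s[2] * np.sin(2 * phi))) * np.sin(theta)
        keep = rng.uniform(0.0, table.density_max, n) < dens
        proposed += n
        accepted += int(keep.sum())
        k = np.flatnonzero(keep)[: size - filled]
        out_t[filled : filled + k.size] = theta[k]
        out_p[filled : filled + k.size] = phi[k]
        filled += k.size
        if filled == size:
            return out_t, out_p
        if proposed >= 100_000 and accepted / proposed < 1e-3:
            raise RuntimeError(
                f"rejection acceptance rate {accepted / proposed:.2e} < 1e-3; "
                "envelope diagnostic: global max greatly exceeds typical density"
            )
    raise RuntimeError("rejection sampling did not converge")


def sample_theta_phi(
    S: np.ndarray, table: PhaseTable, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exact polarized (theta, phi) draw for a batch of photons.

    ``S`` is an (N, 4) array of normalized meridian-frame Stokes vectors.
    theta comes from the inverse CDF of M11 sin(theta); phi | theta from
    f(phi) ∝ 1 + r cos(2phi - delta) with r cos/sin delta = (M12/M11) S1/S2,
    by rejection under the flat envelope 1 + |r|  (acceptance >= 1/2).
    """
    n = S.shape[0]
    theta = table.sample_theta(rng.uniform(0.0, 1.0, n))
    ratio = table.interp("m12", theta) / table.interp("m11", theta)
    c1 = ratio * S[:, 1] / S[:, 0]
    c2 = ratio * S[:, 2] / S[:, 0]
    env = 1.0 + np.sqrt(c1 * c1 + c2 * c2)
    phi = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        cand = rng.uniform(0.0, 2.0 * np.pi, todo.size)
        f = 1.0 + c1[todo] * np.cos(2.0 * cand) + c2[todo] * np.sin(2.0 * cand)
        ok = rng.uniform(0.0, env[todo]) < f
        phi[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return theta, phi
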