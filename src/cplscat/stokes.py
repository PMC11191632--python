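"""Stokes vectors and the reference-frame operations used throughout.

A Stokes vector (S0, S1, S2, S3) describes intensity and polarization with
respect to a stated reference plane: S1 is the excess of linear polarization
parallel to the plane, S2 the excess at 45 degrees, S3 the excess of
right-handed circular polarization.  Rotating the reference plane by an angle
psi about the propagation direction mixes (S1, S2) through 2*psi and leaves
S0 and S3 untouched.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["StokesVector", "rotate_stokes", "apply_sphere_mueller"]

_BOUND_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class StokesVector:
    """Polarization state (S0, S1, S2, S3) relative to a reference plane."""

    s0: float
    s1: float = 0.0
    s2: float = 0.0
    s3: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("S0 (intensity) must be >= 0")
        if self.dop_squared() > 1.0 + _BOUND_TOL:
            raise ValueError(
                "unphysical Stokes vector: S1^2+S2^2+S3^2 exceeds S0^2"
            )

    def dop_squared(self) -> float:
        """(S1^2 + S2^2 + S3^2) / S0^2, the squared degree of polarization."""
        if self.s0 == 0.0:
            return 0.0
        return (self.s1**2 + self.s2**2 + self.s3**2) / self.s0**2

    def rotate(self, psi: float) -> "StokesVector":
        """Stokes vector in a reference frame rotated by ``psi`` (radians)."""
        c, s = np.cos(2.0 * psi), np.sin(2.0 * psi)
        return StokesVector(
            self.s0, c * self.s1 + s * self.s2, -s * self.s1 + c * self.s2, self.s3
        )

    def normalized(self) -> "StokesVector":
        if self.s0 <= 0:
            raise ValueError("cannot normalize a zero-intensity Stokes vector")
        return StokesVector(
            1.0, self.s1 / self.s0, self.s2 / self.s0, self.s3 / self.s0
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3])

    @classmethod
    def rcp(cls, intensity: float = 1.0) -> "StokesVector":
        """Right-handed circularly polarized light (S3 = +S0)."""
        return cls(intensity, 0.0, 0.0, intensity)


def rotate_stokes(S: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Frame rotation applied to an (N, 4) Stokes array; psi shape (N,).

    S1' = cos(2psi) S1 + sin(2psi) S2, S2' = -sin(2psi) S1 + cos(2psi) S2.
    """
    c = np.cos(2.0 * psi)
    s = np.sin(2.0 * psi)
    out = S.copy()
    out[..., 1] = c * S[..., 1] + s * S[..., 2]
    out[..., 2] = -s * S[..., 1] + c * S[..., 2]
    return out


def apply_sphere_mueller(S, m11, m12, m33, m34) -> np.ndarray:
    """Single-sphere Mueller matrix applied to an (N, 4) Stokes array.

    Implements the block-diagonal sphere matrix
        [[m11, m12, 0, 0], [m12, m11, 0, 0],
         [0, 0, m33, m34], [0, 0, -m34, m33]].
    """
    S = np.asarray(S, dtype=float)
    out = np.empty_like(S)
    out[..., 0] = m11 * S[..., 0] + m12 * S[..., 1]
    out[..., 1] = m12 * S[..., 0] + m11 * S[..., 1]
    out[..., 2] = m33 * S[..., 2] + m34 * S[..., 3]
    out[..., 3] = -m34 * S[..., 2] + m33 * S[..., 3]
    return out
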