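"""Wavelength selection for discriminating particle populations by size.

The iso-X depolarization lines turn particle sizing into wavelength choice:
a particle of diameter a sits on the X line at lambda = a / X, where its
scattering depolarizes circular light strongly.  To discriminate two
populations, pick wavelengths where one population sits on a line and the
other sits in a quiet region — e.g. normal (~6 um) versus cancerous
(~11 um) cell nuclei, or red (6-8 um) versus white (12-15 um) blood cells.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .diagram import DiagramGrid
from .single import expected_s3_single

__all__ = [
    "DiscriminationQuery",
    "WavelengthRecommendation",
    "wavelength_on_line",
    "recommend",
    "DEFAULT_LINES",
    "WATER_ABSORPTION_NM",
]

#: active iso-X depolarization lines per detection geometry
DEFAULT_LINES = {
    "reflection": (9.0, 12.0, 22.0),
    "transmission": (9.0, 12.0),
}

#: wavelengths at/above this are flagged for strong water absorption in tissue
WATER_ABSORPTION_NM = 1150.0

#: a size is considered "on" a line when |a/lambda - X| <= this
X_TOLERANCE = 0.5


@dataclasses.dataclass(frozen=True)
class DiscriminationQuery:
    """Two particle populations (sizes or size intervals, um) to discriminate."""

    diameter_a_um: float | tuple[float, float]
    diameter_b_um: float | tuple[float, float]
    lambda_range_nm: tuple[float, float] = (600.0, 1500.0)
    geometry: str = "reflection"

    def __post_init__(self) -> None:
        for d in (self.diameter_a_um, self.diameter_b_um):
            lo, hi = _as_interval(d)
            if lo <= 0 or hi < lo:
                raise ValueError("diameters must be positive, intervals increasing")
        lo, hi = self.lambda_range_nm
        if not 0 < lo < hi:
            raise ValueError("lambda_range_nm must be a positive increasing window")
        if self.geometry not in DEFAULT_LINES:
            raise ValueError("geometry must be reflection or transmission")


@dataclasses.dataclass(frozen=True)
class WavelengthRecommendation:
    """One discriminating wavelength (or band) and its provenance."""

    lambda_nm: float | tuple[float, float]
    selective_for: str  # 'A' | 'B'
    contrast: float
    rationale_line: float  # the iso-X line crossed
    water_absorption_warning: bool = False

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


def _as_interval(d) -> tuple[float, float]:
    if np.isscalar(d):
        return float(d), float(d)
    lo, hi = d
    return float(lo), float(hi)


def wavelength_on_line(a_um: float, X: float) -> float:
    """Wavelength (nm) at which diameter ``a_um`` sits on the iso-X line.

    lambda = 1000 * a / X (um to nm), rounded to the nearest 10 nm.
    """
    if a_um <= 0 or X <= 0:
        raise ValueError("diameter and X must be > 0")
    return round(1000.0 * a_um / X / 10.0) * 10.0


def _diagram_contrast(diagram: DiagramGrid, a_a: float, a_b: float, lam: float) -> float:
    ia = int(np.argmin(np.abs(diagram.axis1 - a_a)))
    ib = int(np.argmin(np.abs(diagram.axis1 - a_b)))
    j = int(np.argmin(np.abs(diagram.axis2 - lam)))
    return float(abs(diagram.values[ia, j] - diagram.values[ib, j]))


def _single_contrast(a_a: float, a_b: float, lam: float, m: float) -> float:
    sa = expected_s3_single(m, a_a * 1000.0 / lam)
    sb = expected_s3_single(m, a_b * 1000.0 / lam)
    return float(abs(sa - sb))


def recommend(
    query: DiscriminationQuery,
    diagram: DiagramGrid | None = None,
    lines: tuple[float, ...] | None = None,
    m: float = 1.59 / 1.33,
) -> list[WavelengthRecommendation]:
    """Wavelengths (point sizes) or bands (size intervals) selective for one population.

    Point sizes: for every active iso-X line, the wavelength putting
    population P on the line qualifies if it lies in the search window and
    the *other* population is at least ``X_TOLERANCE`` away from every
    active line at that wavelength.  Intervals: the band
    [lambda(a_min, X), lambda(a_max, X)] — the diagonal of the rectangle the
    line draws across the interval — qualifies if it fits inside the search
    window and no active line crosses the other population's interval
    anywhere in the band.  Contrast is |S3_A - S3_B| at the (band-center)
    wavelength, from ``diagram`` when given, else from the single-scattering
    expectation.
    """
    lines = lines if lines is not None else DEFAULT_LINES[query.geometry]
    lam_lo, lam_hi = query.lambda_range_nm
    a_int = _as_interval(query.diameter_a_um)
    b_int = _as_interval(query.diameter_b_um)
    out: list[WavelengthRecommendation] = []
    for label, mine, other in (("A", a_int, b_int), ("B", b_int, a_int)):
        if mine == other:
            continue
        for X in lines:
            band = (wavelength_on_line(mine[0], X), wavelength_on_line(mine[1], X))
            if band[0] < lam_lo or band[1] > lam_hi:
                continue
            # does any active line cross the other population inside this band?
            clashes = False
            for Xp in lines:
                o_band = (1000.0 * other[0] / Xp, 1000.0 * other[1] / Xp)
                if o_band[0] <= band[1] and band[0] <= o_band[1]:
                    clashes = True
                    break
            # point-size refinement: other merely near a line also disqualifies
            if not clashes and mine[0] == mine[1] and other[0] == other[1]:
                lam = band[0]
                x_other = 1000.0 * other[0] / lam
                if any(abs(x_other - Xp) <= X_TOLERANCE for Xp in lines):
                    clashes = True
            if clashes:
                continue
            center = 0.5 * (band[0] + band[1])
            if diagram is not None:
                contrast = _diagram_contrast(
                    diagram, np.mean(mine), np.mean(other), center
                )
            else:
                contrast = _single_contrast(np.mean(mine), np.mean(other), center, m)
            out.append(
                WavelengthRecommendation(
                    lambda_nm=band[0] if band[0] == band[1] else band,
                    selective_for=label,
                    contrast=contrast,
                    rationale_line=X,
                    water_absorption_warning=max(band) >= WATER_ABSORPTION_NM,
                )
            )
    return sorted(out, key=lambda r: (np.min(r.lambda_nm), r.selective_for))
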