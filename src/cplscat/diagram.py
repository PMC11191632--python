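"""Parameter sweeps and depolarization diagrams.

A depolarization diagram maps the surviving circular polarization <S3> over
a (particle diameter, wavelength) lattice for a chosen detection geometry.
Because the single-scattering expectation depends on (m, X) only, strong
depolarization organizes along iso-X rays a = X * lambda — the
"depolarization lines" (X = 9, 12, 22 for m = 1.195) that wavelength
selection for particle discrimination is built on.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .mc import MediumOptics, SlabGeometry, simulate
from .single import ExpectedS3Curve, expected_s3_single, N_MEDIUM_DEFAULT

__all__ = [
    "DiagramGrid",
    "DepolarizationLine",
    "McCurve",
    "sweep_expected_s3",
    "sweep_mc_curves",
    "sweep_mc_s3",
    "find_mc_minima",
    "build_diagram",
    "refractive_map",
    "extract_lines",
]

GeometryTag = Literal["single", "reflection", "transmission"]


@dataclasses.dataclass(frozen=True)
class DiagramGrid:
    """Mean S3 over an (axis1, axis2) lattice.

    ``axis1`` is diameter in um (or X), ``axis2`` wavelength in nm (or m);
    ``values[i, j]`` corresponds to (axis1[i], axis2[j]).
    """

    axis1: np.ndarray
    axis2: np.ndarray
    values: np.ndarray
    geometry_tag: GeometryTag
    axis_names: tuple[str, str] = ("diameter_um", "wavelength_nm")
    mc_meta: dict | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.axis1), len(self.axis2)):
            raise ValueError("values shape must be (len(axis1), len(axis2))")
        for ax in (self.axis1, self.axis2):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("axes must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("S3 values must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per lattice cell."""
        a1, a2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        return pd.DataFrame(
            {
                self.axis_names[0]: a1.ravel(),
                self.axis_names[1]: a2.ravel(),
                "s3_mean": self.values.ravel(),
                "geometry": self.geometry_tag,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiagramGrid":
        names = tuple(df.columns[:2])
        axis1 = np.unique(df[names[0]].to_numpy())
        axis2 = np.unique(df[names[1]].to_numpy())
        values = (
            df.pivot(index=names[0], columns=names[1], values="s3_mean")
            .reindex(index=axis1, columns=axis2)
            .to_numpy()
        )
        return cls(axis1, axis2, values, df["geometry"].iloc[0], axis_names=names)


@dataclasses.dataclass(frozen=True)
class DepolarizationLine:
    """An iso-X ray a = X * lambda along which depolarization is strong."""

    X_value: float
    endpoints: tuple[tuple[float, float], tuple[float, float]]  # ((a, λ) at λmin/λmax)
    strength: float  # mean S3 deficit along the line

    @staticmethod
    def from_x(X: float, lambda_min_nm: float, lambda_max_nm: float,
               strength: float = float("nan")) -> "DepolarizationLine":
        return DepolarizationLine(
            X_value=X,
            endpoints=(
                (X * lambda_min_nm / 1000.0, lambda_min_nm),
                (X * lambda_max_nm / 1000.0, lambda_max_nm),
            ),
            strength=strength,
        )


@dataclasses.dataclass(frozen=True)
class McCurve:
    """Monte Carlo <S3>(X) with per-point standard errors and tallies."""

    x_grid: np.ndarray
    mean_s3: np.ndarray
    se: np.ndarray
    n_detected: np.ndarray
    geometry: str

    def as_expected_curve(self) -> ExpectedS3Curve:
        return ExpectedS3Curve(self.x_grid, self.mean_s3)


def sweep_expected_s3(
    m: float, X_grid, n_medium: float = N_MEDIUM_DEFAULT
) -> ExpectedS3Curve:
    """Single-scattering <S3> on an X grid (deterministic quadrature per point)."""
    X_grid = np.asarray(X_grid, dtype=float)
    vals = np.array(
        [expected_s3_single(m, float(X), n_medium=n_medium) for X in X_grid]
    )
    return ExpectedS3Curve(X_grid, vals, m=m)


def sweep_mc_curves(
    X_grid,
    photons: int = 20_000,
    seed: int = 0,
    *,
    wavelength_nm: float = 1000.0,
    mu_a: float = 0.10,
    mu_s: float = 6.86,
    n_particle: float = 1.59,
    n_medium: float = N_MEDIUM_DEFAULT,
    slab: SlabGeometry | None = None,
) -> dict[str, McCurve]:
    """Multiple-scattering <S3>(X) curves for both detection geometries.

    One full slab simulation per grid point at fixed wavelength (default
    1000 nm), diameter a = X * lambda; both detectors are scored in the same
    pass.  The per-point seed is ``seed + point index`` so the curve is
    reproducible cell by cell.
    """
    if photons <= 0:
        raise ValueError("photons must be > 0")
    X_grid = np.asarray(X_grid, dtype=float)
    acc: dict[str, list] = {
        side: [[], [], []] for side in ("reflection", "transmission")
    }
    for i, X in enumerate(X_grid):
        medium = MediumOptics(
            particle_diameter_um=float(X) * wavelength_nm / 1000.0,
            wavelength_nm=wavelength_nm,
            mu_a=mu_a, mu_s=mu_s,
            n_particle=n_particle, n_medium=n_medium,
        )
        result = simulate(medium, geometry=slab, n_photons=photons, seed=seed + i)
        for side, (mean, se, nd) in acc.items():
            tally = result.tallies[side]
            mean.append(tally.mean_s3())
            se.append(tally.se_s3())
            nd.append(tally.n_detected)
    return {
        side: McCurve(
            X_grid, np.array(mean), np.array(se), np.array(nd, dtype=int), side
        )
        for side, (mean, se, nd) in acc.items()
    }


def sweep_mc_s3(X_grid, geometry: str = "reflection", photons: int = 20_000,
                seed: int = 0, **kwargs) -> McCurve:
    """Multiple-scattering <S3>(X) for one detection geometry (see sweep_mc_curves)."""
    if geometry not in ("reflection", "transmission"):
        raise ValueError("geometry must be reflection or transmission")
    return sweep_mc_curves(X_grid, photons=photons, seed=seed, **kwargs)[geometry]


def find_mc_minima(curve: McCurve) -> list[float]:
    """Pronounced dips of a coarse Monte Carlo depolarization curve.

    On MC grids (typical step 0.5 in X) the fringe and trough scales are not
    separable by smoothing, so a dip is called pronounced when it is a local
    minimum whose value lies at least one standard deviation below the mean
    of the whole curve — i.e. it stands out of the curve's own variability.
    Returns dip locations sorted ascending in X.
    """
    from scipy.signal import find_peaks

    y = np.asarray(curve.mean_s3, dtype=float)
    if y.size < 3:
        return []
    idx, _ = find_peaks(-y)
    threshold = y.mean() - y.std()
    return sorted(float(curve.x_grid[i]) for i in idx if y[i] < threshold)


def build_diagram(
    a_grid,
    lambda_grid,
    geometry: GeometryTag = "single",
    photons: int = 20_000,
    seed: int = 0,
    *,
    m: float = 1.59 / 1.33,
    n_medium: float = N_MEDIUM_DEFAULT,
    mu_a: float = 0.10,
    mu_s: float = 6.86,
) -> DiagramGrid:
    """Depolarization diagram over a (diameter um, wavelength nm) lattice.

    For ``geometry='single'`` each cell is the deterministic single-scattering
    expectation; cells sharing the same X = a/lambda are computed once and
    reused (the expectation depends only on (m, X)).  For the MC geometries
    every cell runs one slab simulation with per-cell seed offset.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    values = np.empty((a_grid.size, lambda_grid.size))
    if geometry == "single":
        cache: dict[float, float] = {}
        for i, a in enumerate(a_grid):
            for j, lam in enumerate(lambda_grid):
                X = round(a * 1000.0 / lam, 12)
                if X not in cache:
                    cache[X] = expected_s3_single(m, X, n_medium=n_medium)
                values[i, j] = cache[X]
        meta = None
    elif geometry in ("reflection", "transmission"):
        for i, a in enumerate(a_grid):
            for j, lam in enumerate(lambda_grid):
                medium = MediumOptics(
                    particle_diameter_um=float(a), wavelength_nm=float(lam),
                    mu_a=mu_a, mu_s=mu_s,
                    n_particle=m * n_medium, n_medium=n_medium,
                )
                cell_seed = seed + i * lambda_grid.size + j
                result = simulate(medium, n_photons=photons, seed=cell_seed)
                values[i, j] = result.tallies[geometry].mean_s3()
        meta = {"photons": photons, "base_seed": seed}
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return DiagramGrid(a_grid, lambda_grid, values, geometry, mc_meta=meta)


def refractive_map(
    m_grid, X_grid, n_medium: float = N_MEDIUM_DEFAULT
) -> DiagramGrid:
    """Single-scattering <S3> over a (relative index m, X) lattice.

    Cells with m <= 1 are flagged NaN (index matching scatters nothing and
    the relative-index axis of interest is m > 1).
    """
    m_grid = np.asarray(m_grid, dtype=float)
    X_grid = np.asarray(X_grid, dtype=float)
    values = np.full((X_grid.size, m_grid.size), np.nan)
    for j, m in enumerate(m_grid):
        if m <= 1.0:
            continue
        for i, X in enumerate(X_grid):
            values[i, j] = expected_s3_single(float(m), float(X), n_medium=n_medium)
    return DiagramGrid(
        X_grid, m_grid, values, "single", axis_names=("X", "m")
    )


def extract_lines(
    grid: DiagramGrid,
    prominence: float = 0.004,
    min_rows: float = 0.6,
    cluster_tol: float = 0.5,
    min_separation_x: float = 1.5,
) -> list[DepolarizationLine]:
    """Detect iso-X depolarization lines in a (diameter, wavelength) diagram.

    Per wavelength row, local minima of S3 versus diameter — with fringe
    satellites suppressed by a deepest-wins rule within ``min_separation_x``
    in X — are converted to X = a/lambda; candidates from all rows are
    clustered on the X axis (gap > ``cluster_tol`` starts a new cluster) and
    clusters supported by at least ``min_rows`` of the wavelength rows become
    lines, with X_value the prominence-weighted median member (weak shoulder
    minima carry little weight) and strength the mean S3 deficit at the
    member minima.
    """
    from scipy.signal import find_peaks

    if grid.axis_names != ("diameter_um", "wavelength_nm"):
        raise ValueError("extract_lines expects a (diameter, wavelength) diagram")
    candidates: list[tuple[float, float]] = []  # (X, deficit)
    n_rows = 0
    da = float(np.median(np.diff(grid.axis1))) if grid.axis1.size > 1 else 1.0
    for j, lam in enumerate(grid.axis2):
        col = grid.values[:, j]
        if not np.all(np.isfinite(col)) or col.size < 3:
            continue
        n_rows += 1
        dist = max(int(round(min_separation_x * lam / 1000.0 / da)), 1)
        idx, props = find_peaks(-col, prominence=prominence, distance=dist)
        for i, p in zip(idx, props["prominences"]):
            candidates.append((grid.axis1[i] * 1000.0 / lam, float(p)))
    if not candidates or n_rows == 0:
        return []
    candidates.sort()
    xs = np.array([c[0] for c in candidates])
    deficits = np.array([c[1] for c in candidates])
    # gap-based 1-d clustering in X
    breaks = np.flatnonzero(np.diff(xs) > cluster_tol)
    bounds = np.concatenate([[0], breaks + 1, [xs.size]])
    lines = []
    lam_min, lam_max = float(grid.axis2[0]), float(grid.axis2[-1])
    for k in range(bounds.size - 1):
        members = slice(bounds[k], bounds[k + 1])
        if (bounds[k + 1] - bounds[k]) >= min_rows * n_rows:
            xm, wm = xs[members], deficits[members]
            cum = np.cumsum(wm) - 0.5 * wm
            X_val = float(np.interp(0.5 * wm.sum(), cum, xm))
            lines.append(
                DepolarizationLine.from_x(
                    X_val, lam_min, lam_max, strength=float(np.mean(deficits[members]))
                )
            )
    return sorted(lines, key=lambda L: L.X_value)
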