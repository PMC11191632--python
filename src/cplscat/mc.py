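"""Meridian-plane polarized Monte Carlo transport through a turbid slab.

Photon packets carry position, direction, a meridian-frame Stokes vector and
a statistical weight through a slab of thickness ``depth_mm`` (y down, beam
entering at the origin).  Each free path is exponential with attenuation
mu_t = mu_a + mu_s; at every interaction the weight is multiplied by the
single-scattering albedo mu_s/mu_t (implicit capture) and the scattering
angles (theta, phi) are drawn from the polarization-dependent Mie phase
density.  The Stokes vector is rotated into the scattering plane, multiplied
by the sphere Mueller matrix, renormalized to S0=1, and the local reference
frame is carried along explicitly as an orthonormal triad — algebraically
the meridian-plane bookkeeping, without spherical-trigonometry edge cases.

Exiting packets are scored on strip detectors on the source (reflection) or
opposite (transmission) face; their Stokes vectors are first rotated to the
meridian plane through the surface normal (a fixed laboratory frame).  The
average detected S3 measures how much circular polarization memory survives
the random walk; its dependence on the generalized size parameter X = a/λ
is the quantity of interest.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np

from .mie import OpticalContext
from .phase import PhaseTable, sample_theta_phi
from .stokes import StokesVector, apply_sphere_mueller, rotate_stokes

__all__ = [
    "MediumOptics",
    "SlabGeometry",
    "DetectorRegion",
    "PhotonPacket",
    "DetectionRecord",
    "DetectorTally",
    "SimulationResult",
    "sample_step",
    "simulate",
    "propagate_photon",
    "passage_probability_map",
]


@dataclasses.dataclass(frozen=True)
class MediumOptics:
    """Optical description of the turbid slab contents.

    mu_a, mu_s are the absorption and scattering coefficients in 1/mm
    (defaults 0.10 and 6.86); the particle/wavelength pair fixes the Mie
    kernel through the relative index and size parameter.
    """

    particle_diameter_um: float
    wavelength_nm: float = 1000.0
    mu_a: float = 0.10
    mu_s: float = 6.86
    n_particle: float = 1.59
    n_medium: float = 1.33

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.mu_s <= 0:
            raise ValueError("mu_s must be > 0")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        return self.mu_s / self.mu_t

    @property
    def context(self) -> OpticalContext:
        return OpticalContext(
            wavelength_nm=self.wavelength_nm,
            diameter_um=self.particle_diameter_um,
            n_particle=self.n_particle,
            n_medium=self.n_medium,
        )


@dataclasses.dataclass(frozen=True)
class SlabGeometry:
    """Slab of lateral width ``width_mm`` (x) and thickness ``depth_mm`` (y).

    The beam enters at the origin in the middle of the upper face; y
    increases downward.  Photons crossing x = ±width/2 are terminated as
    escaped; the slab is unbounded in z.
    """

    width_mm: float = 12.0
    depth_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("slab dimensions must be > 0")


@dataclasses.dataclass(frozen=True)
class DetectorRegion:
    """Strip detector on one slab face.

    ``x_range_mm`` bounds the exit-point x coordinate, ``z_half_width_mm``
    the |z| extent (the strip depth mirrors the 2 mm window width by
    default).  All exit angles phi in [0, 90) deg from the surface normal
    are accepted; records keep phi for angle-resolved analysis.
    """

    side: Literal["reflection", "transmission"]
    x_range_mm: tuple[float, float] = None  # type: ignore[assignment]
    z_half_width_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.x_range_mm is None:
            default = (1.0, 3.0) if self.side == "reflection" else (-1.0, 1.0)
            object.__setattr__(self, "x_range_mm", default)
        lo, hi = self.x_range_mm
        if not lo < hi:
            raise ValueError("x_range_mm must be an increasing interval")

    def validate_within(self, geometry: SlabGeometry) -> None:
        hw = geometry.width_mm / 2
        lo, hi = self.x_range_mm
        if lo < -hw or hi > hw:
            raise ValueError("detector x_range must lie within the slab width")


@dataclasses.dataclass
class PhotonPacket:
    """State of one photon packet between interactions."""

    position: np.ndarray
    direction: np.ndarray
    stokes: StokesVector
    weight: float = 1.0
    n_events: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-10:
            raise ValueError("direction must be a unit vector")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class DetectionRecord:
    """One detected exit event, Stokes referenced to the detector frame."""

    exit_point: tuple[float, float]  # (x, z) on the face, mm
    exit_angle_phi: float  # radians from the outward surface normal
    stokes: StokesVector
    weight: float
    n_events: int


def sample_step(mu_t: float, rng: np.random.Generator, size: int | None = None):
    """Exponential free-path length s = -ln(u)/mu_t in mm (u uniform in (0,1])."""
    if mu_t <= 0:
        raise ValueError("mu_t must be > 0")
    u = 1.0 - rng.random(size)  # in (0, 1]
    return -np.log(u) / mu_t


class DetectorTally:
    """Accumulated detection records for one detector region."""

    def __init__(self, region: DetectorRegion):
        self.region = region
        self.exit_x: np.ndarray = np.empty(0)
        self.exit_z: np.ndarray = np.empty(0)
        self.phi: np.ndarray = np.empty(0)
        self.stokes: np.ndarray = np.empty((0, 4))
        self.weight: np.ndarray = np.empty(0)
        self.n_events: np.ndarray = np.empty(0, dtype=int)
        self.photon_id: np.ndarray = np.empty(0, dtype=int)

    def _append(self, ex, ez, phi, S, w, nev, pid) -> None:
        self.exit_x = np.concatenate([self.exit_x, ex])
        self.exit_z = np.concatenate([self.exit_z, ez])
        self.phi = np.concatenate([self.phi, phi])
        self.stokes = np.concatenate([self.stokes, S])
        self.weight = np.concatenate([self.weight, w])
        self.n_events = np.concatenate([self.n_events, nev])
        self.photon_id = np.concatenate([self.photon_id, pid])

    @property
    def n_detected(self) -> int:
        return self.weight.size

    def mean_s3(self) -> float:
        """Intensity-weighted average S3/S0 over all detected exit angles."""
        if self.n_detected == 0:
            raise RuntimeError(
                f"no photons detected on the {self.region.side} detector; "
                "increase the photon count"
            )
        return float(np.average(self.stokes[:, 3], weights=self.weight))

    def se_s3(self) -> float:
        """Standard error of the weighted mean S3."""
        if self.n_detected < 2:
            return float("inf")
        mu = self.mean_s3()
        w = self.weight
        var = np.sum((w * (self.stokes[:, 3] - mu)) ** 2) / np.sum(w) ** 2
        return float(np.sqrt(var))

    def mean_events(self) -> float:
        if self.n_detected == 0:
            return float("nan")
        return float(np.average(self.n_events, weights=self.weight))

    def phi_bin_means(self, bin_deg: float = 10.0):
        """Per-exit-angle-bin weighted mean S3; returns (bin_edges_deg, mean, n)."""
        edges = np.arange(0.0, 90.0 + bin_deg, bin_deg)
        phi_deg = np.degrees(self.phi)
        which = np.digitize(phi_deg, edges) - 1
        means = np.full(edges.size - 1, np.nan)
        counts = np.zeros(edges.size - 1, dtype=int)
        for b in range(edges.size - 1):
            sel = which == b
            counts[b] = int(sel.sum())
            if counts[b]:
                means[b] = np.average(self.stokes[sel, 3], weights=self.weight[sel])
        return edges, means, counts

    def records(self) -> list[DetectionRecord]:
        return [
            DetectionRecord(
                exit_point=(float(self.exit_x[i]), float(self.exit_z[i])),
                exit_angle_phi=float(self.phi[i]),
                stokes=StokesVector(*self.stokes[i]),
                weight=float(self.weight[i]),
                n_events=int(self.n_events[i]),
            )
            for i in range(self.n_detected)
        ]


@dataclasses.dataclass
class SimulationResult:
    """Transport outcome: detector tallies plus the weight ledger."""

    n_photons: int
    tallies: dict[str, DetectorTally]
    absorbed: float
    roulette_killed: float
    roulette_boost: float
    lateral_escape: float
    undetected_exit: float
    max_events_seen: int
    path_events: np.ndarray | None = None  # (id, x, y, weight) per event, optional

    def weight_balance(self) -> float:
        """Detected + escaped + absorbed + killed - roulette boost; equals N exactly."""
        detected = sum(t.weight.sum() for t in self.tallies.values())
        return float(
            detected
            + self.undetected_exit
            + self.lateral_escape
            + self.absorbed
            + self.roulette_killed
            - self.roulette_boost
        )

    def summary(self) -> dict:
        out = {"n_photons": self.n_photons}
        for side, t in self.tallies.items():
            out[side] = {
                "mean_s3": t.mean_s3() if t.n_detected else None,
                "se": t.se_s3() if t.n_detected else None,
                "n_detected": t.n_detected,
                "n_events_mean": t.mean_events(),
            }
        return out


def _initial_state(n: int, incident_angle_deg: float):
    th = math.radians(incident_angle_deg)
    u0 = np.array([math.sin(th), math.cos(th), 0.0])
    epar0 = np.array([math.cos(th), -math.sin(th), 0.0])
    pos = np.zeros((n, 3))
    u = np.tile(u0, (n, 1))
    epar = np.tile(epar0, (n, 1))
    S = np.tile(np.array([1.0, 0.0, 0.0, 1.0]), (n, 1))
    return pos, u, epar, S


def _detector_frame_rotation(S, u, epar, normal):
    """Rotate meridian-frame Stokes vectors to the frame of the exit meridian
    plane through the surface normal (fixed laboratory detector frame)."""
    ndotu = u @ normal
    em = normal[None, :] - ndotu[:, None] * u
    norm = np.linalg.norm(em, axis=1)
    ok = norm > 1e-12
    em[ok] /= norm[ok, None]
    eperp = np.cross(u, epar)
    cos_a = np.einsum("ij,ij->i", em, epar)
    sin_a = np.einsum("ij,ij->i", em, eperp)
    alpha = np.arctan2(sin_a, cos_a)
    alpha[~ok] = 0.0  # exit along the normal: meridian plane degenerate
    return rotate_stokes(S, alpha)


def _transport(
    pos, u, epar, S, w,
    medium: MediumOptics,
    geometry: SlabGeometry,
    detectors: list[DetectorRegion],
    rng: np.random.Generator,
    *,
    table: PhaseTable | None = None,
    weight_threshold: float = 1e-4,
    roulette_survival: float = 0.1,
    max_events: int = 1_000_000,
    record_paths: bool = False,
) -> SimulationResult:
    n0 = pos.shape[0]
    for d in detectors:
        d.validate_within(geometry)
    if table is None:
        ctx = medium.context
        table = PhaseTable.build(ctx.m, ctx.x)
    mu_t = medium.mu_t
    albedo = medium.albedo
    half_width = geometry.width_mm / 2
    depth = geometry.depth_mm

    tallies = {d.side: DetectorTally(d) for d in detectors}
    pid = np.arange(n0)
    nev = np.zeros(n0, dtype=int)
    absorbed = 0.0
    killed = 0.0
    boost = 0.0
    lateral = 0.0
    undetected = 0.0
    max_seen = 0
    path_chunks: list[np.ndarray] = []

    normal_top = np.array([0.0, -1.0, 0.0])
    normal_bot = np.array([0.0, 1.0, 0.0])

    while pos.shape[0]:
        n = pos.shape[0]
        step = sample_step(mu_t, rng, n)
        # parametric distance to each bounding plane along the current direction
        with np.errstate(divide="ignore", invalid="ignore"):
            t_top = np.where(u[:, 1] < 0, -pos[:, 1] / u[:, 1], np.inf)
            t_bot = np.where(u[:, 1] > 0, (depth - pos[:, 1]) / u[:, 1], np.inf)
            t_lat = np.where(
                u[:, 0] > 0,
                (half_width - pos[:, 0]) / u[:, 0],
                np.where(u[:, 0] < 0, (-half_width - pos[:, 0]) / u[:, 0], np.inf),
            )
        t_planes = np.stack([t_top, t_bot, t_lat], axis=1)
        plane = np.argmin(t_planes, axis=1)
        t_exit = t_planes[np.arange(n), plane]
        exits = t_exit <= step

        if np.any(exits):
            te = t_exit[exits]
            ep = pos[exits] + te[:, None] * u[exits]
            eu = u[exits]
            eS = S[exits]
            ew = w[exits]
            eepar = epar[exits]
            enev = nev[exits]
            epid = pid[exits]
            eplane = plane[exits]

            lat_mask = eplane == 2
            lateral += ew[lat_mask].sum()

            for face, nrm, side in (
                (0, normal_top, "reflection"),
                (1, normal_bot, "transmission"),
            ):
                fm = eplane == face
                if not np.any(fm):
                    continue
                Sdet = _detector_frame_rotation(eS[fm], eu[fm], eepar[fm], nrm)
                phi_exit = np.arccos(np.clip(np.abs(eu[fm, 1]), 0.0, 1.0))
                caught = np.zeros(fm.sum(), dtype=bool)
                for d in detectors:
                    if d.side != side:
                        continue
                    lo, hi = d.x_range_mm
                    inside = (
                        (ep[fm, 0] >= lo)
                        & (ep[fm, 0] <= hi)
                        & (np.abs(ep[fm, 2]) <= d.z_half_width_mm)
                        & ~caught
                    )
                    if np.any(inside):
                        tallies[side]._append(
                            ep[fm][inside, 0],
                            ep[fm][inside, 2],
                            phi_exit[inside],
                            Sdet[inside],
                            ew[fm][inside],
                            enev[fm][inside],
                            epid[fm][inside],
                        )
                    caught |= inside
                undetected += ew[fm][~caught].sum()

        # photons that scatter inside the slab
        keep = ~exits
        if not np.any(keep):
            break
        pos = pos[keep] + step[keep, None] * u[keep]
        u = u[keep]
        epar = epar[keep]
        S = S[keep]
        w = w[keep]
        nev = nev[keep]
        pid = pid[keep]

        absorbed += (w * (1.0 - albedo)).sum()
        w = w * albedo

        if record_paths:
            path_chunks.append(
                np.column_stack([pid.astype(float), pos[:, 0], pos[:, 1], w])
            )

        theta, phi = sample_theta_phi(S, table, rng)
        eperp = np.cross(u, epar)
        cphi, sphi = np.cos(phi)[:, None], np.sin(phi)[:, None]
        epar2 = cphi * epar + sphi * eperp
        S = rotate_stokes(S, phi)
        cth, sth = np.cos(theta)[:, None], np.sin(theta)[:, None]
        u_new = cth * u + sth * epar2
        epar = cth * epar2 - sth * u
        u = u_new
        m11 = table.interp("m11", theta)
        S = apply_sphere_mueller(
            S, m11, table.interp("m12", theta),
            table.interp("m33", theta), table.interp("m34", theta),
        )
        S /= S[:, 0:1]

        # defensive re-orthonormalization (drift over >=1e4 events)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        epar -= np.einsum("ij,ij->i", epar, u)[:, None] * u
        epar /= np.linalg.norm(epar, axis=1, keepdims=True)

        nev += 1
        max_seen = max(max_seen, int(nev.max()))
        if max_seen > max_events:
            raise RuntimeError(
                f"photon exceeded {max_events} scattering events (runaway path)"
            )

        low = w < weight_threshold
        if np.any(low):
            survive = rng.random(int(low.sum())) < roulette_survival
            low_idx = np.flatnonzero(low)
            dead = low_idx[~survive]
            alive_low = low_idx[survive]
            killed += w[dead].sum()
            boost += (w[alive_low] * (1.0 / roulette_survival - 1.0)).sum()
            w[alive_low] /= roulette_survival
            keep2 = np.ones(w.size, dtype=bool)
            keep2[dead] = False
            pos, u, epar, S = pos[keep2], u[keep2], epar[keep2], S[keep2]
            w, nev, pid = w[keep2], nev[keep2], pid[keep2]

    return SimulationResult(
        n_photons=n0,
        tallies=tallies,
        absorbed=float(absorbed),
        roulette_killed=float(killed),
        roulette_boost=float(boost),
        lateral_escape=float(lateral),
        undetected_exit=float(undetected),
        max_events_seen=max_seen,
        path_events=np.concatenate(path_chunks) if path_chunks else None,
    )


def default_detectors() -> list[DetectorRegion]:
    return [DetectorRegion("reflection"), DetectorRegion("transmission")]


def simulate(
    medium: MediumOptics,
    geometry: SlabGeometry | None = None,
    detectors: list[DetectorRegion] | None = None,
    n_photons: int = 20_000,
    seed: int = 0,
    *,
    incident_angle_deg: float = 1.0,
    table: PhaseTable | None = None,
    record_paths: bool = False,
    require_detection: bool = True,
    **engine_kwargs,
) -> SimulationResult:
    """Run a full polarized MC simulation; both detectors are scored in one pass.

    Deterministic for a fixed (configuration, seed) pair.  Raises if a
    configured detector catches no photons (unless ``require_detection``
    is disabled).
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be > 0")
    geometry = geometry or SlabGeometry()
    detectors = detectors if detectors is not None else default_detectors()
    rng = np.random.default_rng(seed)
    pos, u, epar, S = _initial_state(n_photons, incident_angle_deg)
    w = np.ones(n_photons)
    result = _transport(
        pos, u, epar, S, w, medium, geometry, detectors, rng,
        table=table, record_paths=record_paths, **engine_kwargs,
    )
    if require_detection:
        for side, tally in result.tallies.items():
            if tally.n_detected == 0:
                raise RuntimeError(
                    f"zero photons detected on the {side} detector; "
                    "increase n_photons or widen the detector"
                )
    return result


def propagate_photon(
    packet: PhotonPacket,
    medium: MediumOptics,
    geometry: SlabGeometry | None = None,
    rng: np.random.Generator | None = None,
    detectors: list[DetectorRegion] | None = None,
    table: PhaseTable | None = None,
) -> DetectionRecord | str:
    """Transport a single packet; returns a DetectionRecord, 'absorbed' or 'escaped'."""
    geometry = geometry or SlabGeometry()
    detectors = detectors if detectors is not None else default_detectors()
    rng = rng if rng is not None else np.random.default_rng()
    s = packet.stokes.normalized()
    u = packet.direction / np.linalg.norm(packet.direction)
    # meridian reference: plane through the direction and the slab normal
    normal = np.array([0.0, 1.0, 0.0])
    em = normal - (normal @ u) * u
    if np.linalg.norm(em) < 1e-12:
        em = np.array([1.0, 0.0, 0.0]) - u[0] * u
    em /= np.linalg.norm(em)
    result = _transport(
        packet.position[None, :].copy(), u[None, :].copy(), em[None, :],
        s.as_array()[None, :], np.array([float(packet.weight)]),
        medium, geometry, detectors, rng, table=table,
    )
    for tally in result.tallies.values():
        if tally.n_detected:
            return tally.records()[0]
    if result.roulette_killed > 0:
        return "absorbed"
    return "escaped"


def passage_probability_map(
    medium: MediumOptics,
    geometry: SlabGeometry | None = None,
    side: str = "reflection",
    n_photons: int = 5000,
    seed: int = 0,
    bins: tuple[int, int] = (60, 30),
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagnostic (x, y) map of path-visit weight for detected photons.

    Accumulates the weight of every scattering event on trajectories that end
    on the requested detector, normalized to a maximum of 1.  Returns
    (x_edges, y_edges, map) with the map indexed [ix, iy].
    """
    geometry = geometry or SlabGeometry()
    result = simulate(
        medium, geometry, n_photons=n_photons, seed=seed,
        record_paths=True, require_detection=False, **kwargs,
    )
    tally = result.tallies[side]
    if tally.n_detected == 0 or result.path_events is None:
        raise RuntimeError(
            f"zero photons detected on the {side} detector; passage map is empty"
        )
    detected_ids = np.unique(tally.photon_id)
    ev = result.path_events
    sel = np.isin(ev[:, 0].astype(int), detected_ids)
    hw = geometry.width_mm / 2
    hist, xe, ye = np.histogram2d(
        ev[sel, 1], ev[sel, 2],
        bins=bins, range=[[-hw, hw], [0.0, geometry.depth_mm]],
        weights=ev[sel, 3],
    )
    peak = hist.max()
    if peak > 0:
        hist /= peak
    return xe, ye, hist
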