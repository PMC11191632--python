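"""Polarized Monte Carlo transport: limits, conservation, determinism."""

import numpy as np
import pytest

from cplscat.config import make_fixture
from cplscat.mc import (
    DetectorRegion,
    MediumOptics,
    PhotonPacket,
    SlabGeometry,
    passage_probability_map,
    propagate_photon,
    sample_step,
    simulate,
)
from cplscat.single import expected_s3_single
from cplscat.stokes import StokesVector


def _run_fixture(profile, seed=0, **overrides):
    cfg = make_fixture(profile)
    return simulate(
        cfg.medium_optics(), cfg.slab_geometry(), cfg.detector_regions(),
        n_photons=overrides.pop("n_photons", cfg.photons), seed=seed, **overrides,
    )


# ------------------------------------------------------------ step length

def test_step_closed_form_and_limits():
    class FakeRng:
        def __init__(self, u):
            self.u = u

        def random(self, size=None):
            return np.full(size, 1.0 - self.u) if size else 1.0 - self.u

    s = sample_step(6.96, FakeRng(np.exp(-1.0)))
    assert s == pytest.approx(1.0 / 6.96, rel=1e-12)
    assert sample_step(6.96, FakeRng(1.0 - 1e-15)) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        sample_step(0.0, FakeRng(0.5))


def test_step_mean_matches_mean_free_path():
    rng = np.random.default_rng(2)
    mu_t = 6.96
    s = sample_step(mu_t, rng, 100_000)
    se = s.std() / np.sqrt(s.size)
    assert abs(s.mean() - 1.0 / mu_t) < 3 * se


# ------------------------------------------------------------- transport

def test_ballistic_limit_thin_slab():
    """mu_s * depth << 1: transmitted light is unscattered, S3 stays +1."""
    result = _run_fixture("thin_slab", seed=4)
    tally = result.tallies["transmission"]
    assert tally.mean_s3() == pytest.approx(1.0, abs=1e-2)


def test_weight_conservation_identity():
    for profile, seed in [("smoke", 1), ("rayleigh", 2), ("thin_slab", 3)]:
        result = _run_fixture(profile, seed=seed, require_detection=False)
        assert result.weight_balance() == pytest.approx(
            result.n_photons, rel=1e-9
        )


def test_identical_seed_reproduces_bitwise():
    r1 = _run_fixture("smoke", seed=9)
    r2 = _run_fixture("smoke", seed=9)
    for side in ("reflection", "transmission"):
        np.testing.assert_array_equal(
            r1.tallies[side].stokes, r2.tallies[side].stokes
        )
        np.testing.assert_array_equal(
            r1.tallies[side].weight, r2.tallies[side].weight
        )


def test_single_scatter_average_matches_expectation():
    """Thin, wide slab with full-surface detectors on both faces: photons with
    exactly one scattering sample the full sphere and exit almost surely, so
    their average S3 must equal the single-scattering expectation (oracle:
    deterministic quadrature).  The wide/thin geometry removes the
    direction-dependent escape bias a 12 x 6 mm slab would introduce."""
    med = MediumOptics(particle_diameter_um=9.0, mu_s=0.05, mu_a=0.0)
    slab = SlabGeometry(width_mm=100.0, depth_mm=0.2)
    det = [
        DetectorRegion("reflection", x_range_mm=(-50.0, 50.0), z_half_width_mm=1e9),
        DetectorRegion("transmission", x_range_mm=(-50.0, 50.0), z_half_width_mm=1e9),
    ]
    result = simulate(med, slab, detectors=det, n_photons=400_000, seed=17)
    s3 = np.concatenate(
        [t.stokes[t.n_events == 1, 3] for t in result.tallies.values()]
    )
    w = np.concatenate(
        [t.weight[t.n_events == 1] for t in result.tallies.values()]
    )
    mean = np.average(s3, weights=w)
    se = np.sqrt(np.sum((w * (s3 - mean)) ** 2)) / np.sum(w)
    expected = expected_s3_single(med.context.m, x=med.context.x)
    assert abs(mean - expected) < 3 * se


def test_rayleigh_regime_reflection_strongly_depolarized():
    """X = 0.1 scatterers randomize circular polarization almost completely."""
    result = _run_fixture("rayleigh", seed=6, n_photons=4000)
    tally = result.tallies["reflection"]
    assert tally.mean_events() > 20
    assert abs(tally.mean_s3()) < 0.2


def test_mean_event_count_grows_with_scattering_coefficient():
    means = []
    for mu_s in (2.0, 4.0, 6.86):
        med = MediumOptics(particle_diameter_um=9.0, mu_s=mu_s)
        result = simulate(med, n_photons=3000, seed=8)
        means.append(result.tallies["reflection"].mean_events())
    assert means[0] < means[1] < means[2]


def test_transmission_exceeds_reflection_at_x11():
    med = MediumOptics(particle_diameter_um=11.0)
    result = simulate(med, n_photons=100_000, seed=30)
    refl = result.tallies["reflection"]
    trans = result.tallies["transmission"]
    gap = trans.mean_s3() - refl.mean_s3()
    assert gap > 3 * np.hypot(refl.se_s3(), trans.se_s3())


def test_direction_vectors_stay_unit():
    """Direction drift stays at machine scale over long random walks."""
    med = MediumOptics(particle_diameter_um=0.5)  # near-isotropic, many events
    result = simulate(med, n_photons=500, seed=12, require_detection=False)
    # exit angles were computed from |u_y| <= 1; reaching here without NaNs
    for t in result.tallies.values():
        assert np.all(np.isfinite(t.phi))
        assert np.all((t.phi >= 0) & (t.phi < np.pi / 2 + 1e-9))


def test_zero_detected_raises():
    med = MediumOptics(particle_diameter_um=9.0)
    tiny = [DetectorRegion("reflection", x_range_mm=(5.98, 5.99),
                           z_half_width_mm=1e-4)]
    with pytest.raises(RuntimeError, match="zero photons"):
        simulate(med, detectors=tiny, n_photons=50, seed=1)


def test_runaway_path_guard():
    med = MediumOptics(particle_diameter_um=9.0)
    with pytest.raises(RuntimeError, match="runaway"):
        simulate(med, n_photons=200, seed=3, max_events=5,
                 require_detection=False)


# -------------------------------------------------------- single packet

def test_propagate_photon_returns_fate():
    med = MediumOptics(particle_diameter_um=9.0)
    rng = np.random.default_rng(40)
    fates = set()
    for _ in range(30):
        packet = PhotonPacket(
            position=np.zeros(3),
            direction=np.array([0.0, 1.0, 0.0]),
            stokes=StokesVector.rcp(),
        )
        out = propagate_photon(packet, med, rng=rng)
        fates.add(out if isinstance(out, str) else "detected")
    assert fates <= {"detected", "absorbed", "escaped"}
    assert "escaped" in fates or "detected" in fates


# ----------------------------------------------------------- passage map

def test_passage_map_reflection_peak_in_upper_half():
    med = MediumOptics(particle_diameter_um=10.0)
    xe, ye, hist = passage_probability_map(med, side="reflection",
                                           n_photons=4000, seed=5)
    assert hist.max() == pytest.approx(1.0)
    ix, iy = np.unravel_index(np.argmax(hist), hist.shape)
    x_peak = 0.5 * (xe[ix] + xe[ix + 1])
    y_peak = 0.5 * (ye[iy] + ye[iy + 1])
    assert y_peak < 3.0  # upper half of the 6 mm slab
    assert -1.0 <= x_peak <= 4.0  # between source and detector strip


def test_passage_map_transmission_spans_slab_depth():
    med = MediumOptics(particle_diameter_um=10.0)
    xe, ye, hist = passage_probability_map(med, side="transmission",
                                           n_photons=4000, seed=5)
    column = hist.sum(axis=0)
    assert np.all(column > 0)  # visited every depth layer on the way down


def test_passage_map_zero_detection_is_an_error():
    med = MediumOptics(particle_diameter_um=10.0, mu_s=0.001, mu_a=0.0)
    with pytest.raises(RuntimeError):
        passage_probability_map(med, side="reflection", n_photons=20, seed=2)
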