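# Methods

`cplscat` simulates what happens to circularly polarized light (CPL) that
scatters off spherical particles in a turbid slab, at two levels: the exact
single-scattering Mie solution, and a polarized Monte Carlo random walk that
compounds many such events. The quantity tracked throughout is S3, the
circular component of the Stokes vector; its survival encodes the ratio of
particle diameter to wavelength.

## Single-sphere model

For a homogeneous sphere the scattered and incident Stokes vectors are
related by a block-diagonal Mueller matrix with four independent elements

    M11 = (|S2|^2 + |S1|^2)/2,  M12 = (|S2|^2 - |S1|^2)/2,
    M33 = Re(S2 S1*),           M34 = Im(S2 S1*),

where S1(theta), S2(theta) are the Mie amplitude functions built from the
coefficients a_n, b_n and the angle functions pi_n, tau_n. The
parametrization is the standard pair

* relative refractive index `m = n_particle / n_medium`, and
* size parameter `x = pi a n_medium / lambda` (`a` is the **diameter**, so
  this equals the conventional radius-based `2 pi r n / lambda`),

with the *generalized* size parameter `X = a / lambda = x / (pi n_medium)`
used as the axis of all diagrams, because for fixed `m` every single-
scattering observable depends on `(m, X)` only.

Numerical choices:

* Truncation: Wiscombe's rule `n_max = ceil(x + 4.05 x^(1/3) + 2)`.
  The last retained term is ~1e-10 relative at x ≈ 40 — ample for the
  1e-8 reproducibility the convergence tests assert.
* Coefficients by downward recurrence of the logarithmic derivative
  `D_n(mx)` (started 16 orders above the truncation) with Riccati–Bessel
  `psi_n`, `xi_n` by scipy's spherical Bessel routines; validated to ~3e-15
  against a 40-digit direct evaluation (mpmath).
* Convention: `xi_n = x (j_n - i y_n)`. All intensity and circular-
  polarization observables are convention-independent; only the sign pair
  (M34, Im a_n) is tied to it.
* Angle functions by the usual upward recurrences, seeds `pi_0 = 0`,
  `pi_1 = 1`.
* Angular grids resolve the ~pi/x interference fringes: step
  `min(0.1 deg, 180 deg / 20x)` with both endpoints exact.

## Expected S3 of one scattering event

For circular incidence the probability of scattering into solid angle
`dOmega` is proportional to `M11 sin(theta)`, and the emitted degree of
circular polarization at that angle is `M33/M11`. The expectation over one
event is therefore

    <S3>(m, X) = Int M33 sin dtheta / Int M11 sin dtheta,

evaluated by trapezoidal quadrature on the fringe-resolving grid (stable to
~1e-5 under 4x refinement). It is exactly +-1 at theta = 0/pi for every
(m, x), vanishes in the Rayleigh limit (the 2cos/(1+cos^2) lobe integrates
to zero), and dips at specific X values — the depolarization troughs.

**Trough detection.** The exact curve carries two scales: interference
fringes (period 0.1–0.4 in X, amplitude up to ~0.02) riding on broad troughs
spaced 3–4 apart. `find_depolarization_minima` separates them by a 0.3-wide
moving average, a prominence floor of 0.004 (above the residual fringe level
after smoothing, below the weakest broad trough), and a deepest-wins rule
within 2.0 in X (half the smallest inter-trough spacing), in that order. At
m = 1.195 on X in [1, 30] this finds troughs at X ≈ 4.9, 8.7, 12.3, 16.0,
20.6, 23.6, 25.7. The second and third — the X = 9 and X = 12 lines — are
the landmarks the applications use. Mid-range trough centers are genuinely
soft: the 15–24 band is a dense fringe field whose eyeballed dip positions
depend on sampling, so reported centers there carry ~1 in X of systematic
leeway.

## Polarized Monte Carlo transport

Photon packets start at the origin of a `12 x 6` mm slab (y down), direction
tilted 1 degree from the inward normal, Stokes (1, 0, 0, +1) (right-circular).
Default optics: `mu_a = 0.10 mm^-1`, `mu_s = 6.86 mm^-1`, indices 1.59/1.33.
The transport cycle:

1. exponential free path `s = -ln(u) / mu_t`;
2. boundary test against the two faces and the lateral edges `x = +-6 mm`
   (lateral crossers are dropped as escaped; face crossers are scored);
3. implicit capture: weight times albedo `mu_s/mu_t` per event, threshold
   1e-4 with Russian roulette survival 0.1;
4. scattering angles `(theta, phi)` from the polarized phase density
   `P ∝ [M11 S0 + M12 (S1 cos 2phi + S2 sin 2phi)] sin(theta)`;
5. meridian-frame update: rotate the Stokes reference by phi about the
   direction, deflect by theta in the new scattering plane, apply the sphere
   Mueller matrix, renormalize S0 to 1.

The reference frame is carried as an explicit orthonormal triad
(e_par, e_perp, u) and re-orthonormalized every event, which is the
meridian-plane bookkeeping without spherical-trigonometry edge cases; the
helicity flip on backscatter emerges from the M33/M34 block, nothing is
hand-coded. Transport is fully 3-D; detectors are strips (reflection
x in [1, 3] mm, transmission x in [-1, 1] mm, |z| <= 1 mm mirroring the 2 mm
window width) accepting all exit angles below 90 degrees, and detected
Stokes vectors are rotated to the meridian plane through the surface normal
before intensity-weighted averaging (S3 itself is rotation-invariant, so
this matters only for the stored S1/S2). Index-matched boundaries: no
Fresnel reflection or refraction (`fresnel: off` in spirit; the boundary
model is deliberately minimal and isolated in the exit handling).

**Sampling.** The engine draws theta from the exact marginal
`M11 sin(theta)` by tabulated inverse CDF and phi from the conditional
`1 + r cos(2phi - delta)` by rejection under the flat envelope `1 + |r|`
(acceptance >= 1/2). This is draw-for-draw the same joint density as the
textbook global-envelope rejection method, which is also provided
(`rejection_sample_angles`) and distribution-tested against the engine
sampler, but whose acceptance collapses like the inverse forward-peak
enhancement at x ≈ 25–60. One seeded generator drives a run; all photon
batches are advanced vectorized, and a fixed (config, seed) pair reproduces
output byte for byte.

**Weight ledger.** Implicit capture and roulette conserve weight pathwise
once the roulette boost `w (1/p - 1)` of survivors is booked explicitly;
`SimulationResult.weight_balance()` closes to the launched count to 1e-9,
and the tests assert it.

## Monte Carlo depolarization curves and diagrams

`sweep_mc_curves` runs one slab simulation per X at fixed wavelength
(1000 nm, so a = X um), scoring both detectors in the same pass, with
per-point seed offsets. Because every scattering event in a monodisperse
medium samples the same X, multiple scattering raises the single-event
curve approximately to the power of the event count: troughs deepen from
~0.93 to ~0.1–0.2 in reflection, and the single-event fringes are amplified
into real dips as well (a reproducible dip near X = 10.5 sits between the
9 and 12 troughs at 2e4 photons — it is physics, not noise). On such coarse
curves smoothing cannot separate fringe from trough, so `find_mc_minima`
calls a dip pronounced when it is a local minimum at least one curve
standard deviation below the curve mean; with the default grid
(X in [6, 14], step 0.5, 2e4 photons/point) this yields {9.0, 10.5, 12.0}
stably across seeds.

Diagrams (`build_diagram`) evaluate mean S3 over a (diameter, wavelength)
lattice — deterministic and X-deduplicated for the single-scattering
geometry, one MC run per cell otherwise (default lattice 0.25 um x 25 nm,
2e4 photons/cell). `extract_lines` finds the iso-X depolarization lines by
per-row minima (with the same deepest-wins fringe suppression), gap
clustering on a/lambda and a prominence-weighted median, recovering X ≈ 8.7
and 12.0 lines from the analytic diagram.

## Wavelength selection

`wavelength_on_line(a, X) = 1000 a / X` rounded to 10 nm places a diameter
on a line; `recommend` applies the rectangle rule for size intervals: the
band `[lambda(a_min, X), lambda(a_max, X)]` qualifies when it fits in the
search window and no active line crosses the competing interval inside it.
Active lines default to {9, 12, 22} in reflection and {9, 12} in
transmission (the X = 22 line is weak there and the broad X ~ 5 region is
advisory). Recommendations at or beyond 1150 nm carry a water-absorption
warning; absorption spectra themselves are out of scope. For the
(11 um, X = 9) crossing the exact ray gives 1220 nm while diagram troughs
read nearer 1240 nm; the analytic ray value is reported.

## What the defaults emulate, and known limitations

The defaults are the study conditions: fixed optical coefficients (no
spectral mu_a/mu_s), monodisperse spheres, no birefringence, no Fresnel
boundaries, pencil-beam illumination. Real tissue has size dispersion
(which smooths the fringe scale but keeps the broad troughs), spectrally
varying absorption (water absorption is only flagged, not modeled), and
birefringent structures — so passing tests show the geometry of the
depolarization landscape, not absolute S3 levels in tissue.

Two published claims about that landscape did not survive exact computation
and are deliberately left as failing checks rather than quietly relaxed:
(i) the mid-range single-scattering trough centers come out near
16.0/20.6/23.6 rather than the commonly quoted 17/19/22 reading (the
5/9/12/26 landmarks reproduce within +-0.5); (ii) in full 3-D transport with all-exit-angle
averaging, transmission-side S3 exceeds reflection-side S3 on only ~40% of
the X grid, not >=80% — the ordering holds at the X = 11 comparison point
and under a <40 degree exit-angle cut, suggesting it depends on the
detection model (or a 2-D transport picture) rather than on the medium.

Problem sizes used by the shipped checks: X step 0.05 (581 quadrature
points) for the single-scattering curve; 17 MC grid points at 2e4 photons
each for the multiple-scattering curve; refractive-index maps at X step
0.25–0.5. These run in well under ten minutes on one core; finer lattices
scale linearly through the same entry points.
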